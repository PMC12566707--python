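"""Phylogenetic community structure: MPD, MNTD and the NRI/NTI z-scores.

NRI and NTI are standardized effect sizes of the observed mean pairwise
distance (MPD) and mean nearest-taxon distance (MNTD) against a null
distribution obtained with the taxa-labels randomization: community size is
held fixed while species identities are shuffled uniformly across the pool
(the label set of the distance matrix).  Both carry a leading -1, so positive
values indicate phylogenetic clustering and negative values overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ValidationError


@dataclass(frozen=True)
class PhyloStructure:
    """Observed and null MPD/MNTD with the derived NRI/NTI z-scores.

    ``degenerate`` is set when the z-scores are conventions rather than
    measurements: a community of fewer than two species, or a null
    distribution with zero spread (e.g. community == pool).
    """

    mpd_obs: float
    mntd_obs: float
    mpd_null_mean: float
    mpd_null_sd: float
    mntd_null_mean: float
    mntd_null_sd: float
    nri: float
    nti: float
    n_randomizations: int
    seed: int | None
    degenerate: bool = False


def _community_indices(d: pd.DataFrame, community: Iterable[str]) -> np.ndarray:
    community = list(dict.fromkeys(community))
    labels = list(d.index)
    pos = {l: i for i, l in enumerate(labels)}
    missing = [c for c in community if c not in pos]
    if missing:
        raise ValidationError(f"community members not in distance matrix: {missing}")
    return np.array([pos[c] for c in community], dtype=int)


def mpd(d: pd.DataFrame, community: Iterable[str]) -> float:
    """Mean patristic distance over all unordered species pairs (unweighted)."""
    idx = _community_indices(d, community)
    if idx.size < 2:
        raise DegenerateInputError("MPD undefined for fewer than 2 species")
    sub = d.to_numpy()[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(sub[iu].mean())


def mntd(d: pd.DataFrame, community: Iterable[str]) -> float:
    """Mean distance from each member to its nearest co-occurring relative."""
    idx = _community_indices(d, community)
    if idx.size < 2:
        raise DegenerateInputError("MNTD undefined for fewer than 2 species")
    sub = d.to_numpy()[np.ix_(idx, idx)].astype(float).copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _metrics_from_indices(dm: np.ndarray, idx: np.ndarray) -> tuple[float, float]:
    sub = dm[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    m = sub[iu].mean()
    sub = sub.copy()
    np.fill_diagonal(sub, np.inf)
    return float(m), float(sub.min(axis=1).mean())


def ses_structure(
    d: pd.DataFrame,
    community: Iterable[str],
    n_rand: int = 999,
    seed: int | None = None,
) -> PhyloStructure:
    """NRI/NTI of one community against the taxa-labels null model.

    Null replicates draw ``len(community)`` labels uniformly without
    replacement from the pool (all labels of ``d``) — the marginal
    distribution a uniform permutation of the label set induces on the
    community's identities.  ``NRI = -(MPD_obs - mean_null)/sd_null`` and
    likewise NTI with MNTD.

    Degenerate cases return z-scores of 0 with ``degenerate=True``:
    fewer than 2 community members (no pairwise structure exists), or a
    null sd of 0 (community spans the whole pool).
    """
    if n_rand < 1:
        raise ValidationError("n_rand must be >= 1")
    idx = _community_indices(d, community)
    pool = d.shape[0]
    if d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if idx.size < 2:
        return PhyloStructure(
            mpd_obs=float("nan"), mntd_obs=float("nan"),
            mpd_null_mean=float("nan"), mpd_null_sd=0.0,
            mntd_null_mean=float("nan"), mntd_null_sd=0.0,
            nri=0.0, nti=0.0, n_randomizations=n_rand, seed=seed, degenerate=True,
        )
    dm = d.to_numpy().astype(float)
    mpd_obs, mntd_obs = _metrics_from_indices(dm, idx)
    rng = np.random.default_rng(seed)
    null_mpd = np.empty(n_rand)
    null_mntd = np.empty(n_rand)
    for k in range(n_rand):
        rand_idx = rng.choice(pool, size=idx.size, replace=False)
        null_mpd[k], null_mntd[k] = _metrics_from_indices(dm, rand_idx)
    mpd_mean = float(null_mpd.mean())
    mntd_mean = float(null_mntd.mean())
    mpd_sd = float(null_mpd.std(ddof=1)) if n_rand > 1 else 0.0
    mntd_sd = float(null_mntd.std(ddof=1)) if n_rand > 1 else 0.0
    # a point-mass null (community == pool) leaves only float jitter in the sd
    tiny_mpd = mpd_sd <= 1e-10 * max(1.0, abs(mpd_mean))
    tiny_mntd = mntd_sd <= 1e-10 * max(1.0, abs(mntd_mean))
    degenerate = tiny_mpd or tiny_mntd
    nri = 0.0 if tiny_mpd else -1.0 * (mpd_obs - mpd_mean) / mpd_sd
    nti = 0.0 if tiny_mntd else -1.0 * (mntd_obs - mntd_mean) / mntd_sd
    return PhyloStructure(
        mpd_obs=mpd_obs, mntd_obs=mntd_obs,
        mpd_null_mean=mpd_mean, mpd_null_sd=mpd_sd,
        mntd_null_mean=mntd_mean, mntd_null_sd=mntd_sd,
        nri=float(nri), nti=float(nti),
        n_randomizations=n_rand, seed=seed, degenerate=degenerate,
    )


def plot_seed(master_seed: int, plot_id: str) -> int:
    """Deterministic per-plot child seed: independent of plot iteration order."""
    import zlib

    return (int(master_seed) ^ zlib.crc32(plot_id.encode())) % (2**31 - 1)
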