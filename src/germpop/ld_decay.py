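"""Chromosome-wise linkage-disequilibrium decay: pairwise r^2 within a
distance window, expanding graduated distance binning, and threshold-crossing
decay-distance estimation.

r^2 is the squared Pearson correlation of unphased dosage vectors over
pairwise-complete samples — the genotype-count estimator used by standard
LD tools — so no phasing is required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: Columns of the pair table produced by :func:`pairwise_r2`.
LDPAIR_COLUMNS = ("chrom", "pos_i", "pos_j", "distance_bp", "r2")


@dataclass
class LDBinning:
    """Expanding-width distance bins with per-bin mean r^2.

    Bins are half-open ``(edges[k], edges[k+1]]``; empty bins carry count 0
    and NaN mean.
    """

    edges: np.ndarray
    mean_r2: np.ndarray
    counts: np.ndarray
    midpoints: np.ndarray


def expanding_scheme(max_dist: int = 5_000_000) -> np.ndarray:
    """Default expanding graduated distance scale: 10 kb bins to 100 kb,
    50 kb bins to 1 Mb, 250 kb bins to 5 Mb, truncated at ``max_dist``."""
    edges = [0]
    for stop, step in ((100_000, 10_000), (1_000_000, 50_000), (5_000_000, 250_000)):
        while edges[-1] < min(stop, max_dist):
            edges.append(min(edges[-1] + step, max_dist, stop))
        if edges[-1] >= max_dist:
            break
    return np.array(sorted(set(edges)), dtype=np.int64)


def pairwise_r2(matrix: GenotypeMatrix, chrom: str,
                max_dist: int = 5_000_000) -> pd.DataFrame:
    """All locus pairs on ``chrom`` within ``max_dist``, as a DataFrame with
    columns :data:`LDPAIR_COLUMNS`.

    Pairs where either locus is monomorphic over the pairwise-complete
    samples (or with <2 complete samples) are skipped.
    """
    on_chrom = np.flatnonzero(matrix.chroms() == chrom)
    if len(on_chrom) < 2:
        logger.warning("pairwise_r2: fewer than 2 loci on %s", chrom)
        return pd.DataFrame(columns=LDPAIR_COLUMNS)
    sub = matrix.calls[:, on_chrom].astype(np.float64)
    pos = matrix.positions()[on_chrom]
    order = np.argsort(pos, kind="stable")
    sub, pos = sub[:, order], pos[order]
    ok = sub != MISSING
    subz = np.where(ok, sub, 0.0)

    rows_i, rows_j, rows_r2 = [], [], []
    L = len(pos)
    for i in range(L - 1):
        j_hi = int(np.searchsorted(pos, pos[i] + max_dist, side="right"))
        if j_hi <= i + 1:
            continue
        sl = slice(i + 1, j_hi)
        x, mx = subz[:, i], ok[:, i]
        y, my = subz[:, sl], ok[:, sl]
        m = mx[:, None] & my
        n = m.sum(axis=0).astype(float)
        xm = np.where(m, x[:, None], 0.0)
        ym = np.where(m, y, 0.0)
        sx, sy = xm.sum(axis=0), ym.sum(axis=0)
        sxx = (xm ** 2).sum(axis=0)
        syy = (ym ** 2).sum(axis=0)
        sxy = (xm * ym).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            var_x = n * sxx - sx ** 2
            var_y = n * syy - sy ** 2
            r2 = (n * sxy - sx * sy) ** 2 / (var_x * var_y)
        valid = (n >= 2) & (var_x > 0) & (var_y > 0)
        jj = np.flatnonzero(valid)
        rows_i.append(np.full(len(jj), i))
        rows_j.append(jj + i + 1)
        rows_r2.append(r2[jj])

    if not rows_i:
        return pd.DataFrame(columns=LDPAIR_COLUMNS)
    ii = np.concatenate(rows_i)
    jj = np.concatenate(rows_j)
    r2v = np.concatenate(rows_r2)
    return pd.DataFrame({
        "chrom": chrom,
        "pos_i": pos[ii],
        "pos_j": pos[jj],
        "distance_bp": pos[jj] - pos[ii],
        "r2": np.clip(r2v, 0.0, 1.0),
    })


def bin_ld(pairs: pd.DataFrame, scheme: np.ndarray | None = None) -> LDBinning:
    """Unweighted mean r^2 per half-open distance bin ``(lo, hi]``."""
    if scheme is None:
        scheme = expanding_scheme()
    edges = np.asarray(scheme, dtype=np.int64)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    dist = pairs["distance_bp"].to_numpy()
    if len(dist) and dist.max() > edges[-1]:
        raise ValueError(
            f"pair distance {dist.max()} exceeds last bin edge {edges[-1]}; "
            "filter pairs upstream"
        )
    # half-open (lo, hi]: a distance equal to an edge belongs to the bin below
    which = np.searchsorted(edges, dist, side="left") - 1
    which = np.clip(which, 0, len(edges) - 2)
    n_bins = len(edges) - 1
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=pairs["r2"].to_numpy(), minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    means[counts == 0] = np.nan
    mids = (edges[:-1] + edges[1:]) / 2.0
    return LDBinning(edges=edges, mean_r2=means,
                     counts=counts.astype(np.int64), midpoints=mids)


def decay_distance(binning: LDBinning,
                   r2_threshold: float) -> tuple[float | None, str]:
    """Distance (bp) where the binned mean r^2 decays through a threshold.

    Scans non-empty bins in distance order for the first adjacent pair whose
    means cross from >= threshold to < threshold and interpolates linearly
    between the bin midpoints.  Returns ``(distance, "ok")``,
    ``(0.0, "below_at_origin")`` when already below in the first non-empty
    bin, or ``(None, "not_reached")``.
    """
    nz = np.flatnonzero(binning.counts > 0)
    if len(nz) < 2:
        raise ValueError("decay_distance requires >=2 non-empty bins")
    means = binning.mean_r2[nz]
    mids = binning.midpoints[nz]
    if means[0] < r2_threshold:
        return 0.0, "below_at_origin"
    for k in range(len(nz) - 1):
        if means[k] >= r2_threshold and means[k + 1] < r2_threshold:
            frac = (means[k] - r2_threshold) / (means[k] - means[k + 1])
            return float(mids[k] + frac * (mids[k + 1] - mids[k])), "ok"
    return None, "not_reached"
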