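"""Half-molecule Monte Carlo estimation of cyclization J-factors.

The J-factor is the probability density of the far end of the molecule
(fictitious frame N+1) at perfect closure -- position 0, identity
orientation -- expressed as a concentration.  It is estimated by counting
how many of ``M^2`` molecules, formed by pairing ``M`` sampled first halves
with ``M`` sampled second halves, land in a small closure region, and
dividing by the region's volume:

    J = hits / (M^2 * (4/3) pi eps^3 * V_rot(delta))

with the rotational volume taken under the normalized Haar measure.  A
first half spanning steps ``1..m-1`` contributes end state ``(r_1:m,
T_1:m)``; a second half spans ``m..N`` with end state ``(r_m:N+1,
T_m:N+1)``.  The pair closes translationally when

    | r_m:N+1 - (-T_1:m^-1 r_1:m) | <= eps

(which equals the lab-frame end-to-end distance of the glued molecule), and
rotationally when the SO(3) distance of ``T_1:m T_m:N+1`` from the identity
is at most ``delta``.  Candidate pairs are pruned by spatial cube binning
before any distance is computed, which makes the all-pairs count exact but
far cheaper than brute force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from ._quat import quat_multiply, quat_rotate
from .elastic import MoleculeSpec, sample_end_states
from .so3 import ClosureTolerances

__all__ = [
    "NM_PER_INV_CUBIC_ANGSTROM",
    "HalfEnsemble",
    "BinGrid",
    "JEstimate",
    "generate_half_ensemble",
    "pair_and_count",
    "brute_force_count",
    "estimate_J",
    "compute_J",
    "default_split",
    "cyclization_profile",
    "CyclizationProfile",
]

_AVOGADRO = 6.02214076e23
#: 1 per cubic angstrom expressed in nanomolar.
NM_PER_INV_CUBIC_ANGSTROM = 1e36 / _AVOGADRO


@dataclass
class HalfEnsemble:
    """M sampled end states of one half of a molecule.

    ``end_pos`` holds ``r_m:N+1`` for second halves and the pre-rotated
    ``-T_1:m^-1 r_1:m`` for first halves, so that pairing is a plain
    nearest-neighbour problem in R^3.  ``end_quat`` holds the half's net
    rotation as scalar-first quaternions.
    """

    which: str
    M: int
    end_pos: np.ndarray
    end_quat: np.ndarray
    split_m: int
    N: int
    seed: object = None

    def __post_init__(self):
        if self.which not in ("first", "second"):
            raise ValueError("which must be 'first' or 'second'")
        if self.end_pos.shape != (self.M, 3) or self.end_quat.shape != (self.M, 4):
            raise ValueError("end state arrays have wrong shape")


def generate_half_ensemble(
    spec: MoleculeSpec,
    which: str,
    split_m: int,
    M: int,
    seed,
) -> HalfEnsemble:
    """Sample M independent half-molecules and store their end states.

    ``split_m`` is the frame index where the molecule is cut: the first half
    covers steps ``1..split_m-1``, the second ``split_m..N``.
    """
    if not 1 < split_m < spec.N + 1:
        raise ValueError(f"split_m must lie in (1, N+1), got {split_m}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if which == "first":
        first_step, n_steps = 1, split_m - 1
    elif which == "second":
        first_step, n_steps = split_m, spec.N - split_m + 1
    else:
        raise ValueError("which must be 'first' or 'second'")
    pos, quat = sample_end_states(spec, first_step, n_steps, M, rng)
    if which == "first":
        conj = quat * np.array([1.0, -1.0, -1.0, -1.0])
        pos = -quat_rotate(conj, pos)
    return HalfEnsemble(which, M, pos, quat, split_m, spec.N, seed)


@dataclass(frozen=True)
class BinGrid:
    """Spatial binning layout for candidate-pair pruning.

    ``n_z_bins`` slabs across ``z_range`` plus square x/y bins of width
    ``xy_bin_width``.  Correctness requires every bin dimension to be at
    least ``eps`` so that all matches lie in adjacent bins; this is enforced
    at pairing time.
    """

    n_z_bins: int = 128
    xy_bin_width: float = 30.0
    z_range: tuple = (0.0, 3840.0)

    @property
    def z_bin_width(self) -> float:
        return (self.z_range[1] - self.z_range[0]) / self.n_z_bins

    @classmethod
    def for_ensembles(
        cls,
        first: HalfEnsemble,
        second: HalfEnsemble,
        eps: float,
        n_z_bins: int = 128,
    ) -> "BinGrid":
        """Grid covering the observed z-range, capped so bins stay >= eps."""
        z = np.concatenate([first.end_pos[:, 2], second.end_pos[:, 2]])
        lo, hi = float(z.min()) - 1e-9, float(z.max()) + 1e-9
        span = max(hi - lo, eps)
        n = min(int(n_z_bins), max(1, int(math.floor(span / eps))))
        return cls(n, float(eps), (lo, lo + span))

    def cell_indices(self, pos: np.ndarray) -> np.ndarray:
        """Integer (ix, iy, iz) cube indices of points."""
        out = np.empty(pos.shape, dtype=np.int64)
        out[:, 0] = np.floor(pos[:, 0] / self.xy_bin_width)
        out[:, 1] = np.floor(pos[:, 1] / self.xy_bin_width)
        out[:, 2] = np.floor((pos[:, 2] - self.z_range[0]) / self.z_bin_width)
        return out

    def z_bin_index(self, pos: np.ndarray) -> np.ndarray:
        return np.floor((pos[:, 2] - self.z_range[0]) / self.z_bin_width).astype(
            np.int64
        )


_KEY_BASE = np.int64(1) << 21
_KEY_OFF = np.int64(1) << 20


def _cell_keys(idx: np.ndarray) -> np.ndarray:
    return ((idx[:, 0] + _KEY_OFF) * _KEY_BASE + (idx[:, 1] + _KEY_OFF)) * _KEY_BASE + (
        idx[:, 2] + _KEY_OFF
    )


def pair_and_count(
    first: HalfEnsemble,
    second: HalfEnsemble,
    tol: ClosureTolerances,
    grid: BinGrid | None = None,
    max_chunk_pairs: int = 1 << 24,
    with_variance: bool = False,
) -> int | tuple[int, float]:
    """Count closing (first, second) pairs; exact, with cube-bin pruning.

    Candidates are restricted to bins at most one step apart in z, x and y,
    then filtered by the cheap z-difference test, the full Euclidean test,
    and finally the SO(3) test.  The count equals the brute-force all-pairs
    count for any grid whose bins are at least eps wide.

    With ``with_variance=True`` also returns a variance estimate for the
    hit count.  The M^2 glued molecules share halves, so hits are a
    U-statistic whose variance exceeds Poisson; for rare closures it is
    estimated as ``hits + sum_i h_i (h_i - 1) + sum_j h_j (h_j - 1)`` from
    the per-half match multiplicities h_i, h_j.
    """
    if first.which != "first" or second.which != "second":
        raise ValueError("pass the ensembles as (first, second)")
    if first.split_m != second.split_m or first.N != second.N:
        raise ValueError("ensembles come from different molecules or splits")
    if grid is None:
        grid = BinGrid.for_ensembles(first, second, tol.eps)
    if grid.xy_bin_width < tol.eps - 1e-12 or grid.z_bin_width < tol.eps - 1e-12:
        raise ValueError(
            "bin width below eps: adjacent-bin search would miss matches"
        )

    kf = _cell_keys(grid.cell_indices(first.end_pos))
    order_f = np.argsort(kf, kind="stable")
    kf_sorted = kf[order_f]
    pf = first.end_pos[order_f]
    qf = first.end_quat[order_f]

    ks = _cell_keys(grid.cell_indices(second.end_pos))
    order_s = np.argsort(ks, kind="stable")
    ks_sorted = ks[order_s]
    ps = second.end_pos[order_s]
    qs = second.end_quat[order_s]
    ucell, ustart, ucount = np.unique(
        ks_sorted, return_index=True, return_counts=True
    )

    eps2 = tol.eps * tol.eps
    w_min = math.sqrt(max(0.0, 1.0 - tol.delta * tol.delta))
    hits = 0
    h_first = np.zeros(first.M, dtype=np.int64)
    h_second = np.zeros(second.M, dtype=np.int64)
    offsets = [
        dx * _KEY_BASE * _KEY_BASE + dy * _KEY_BASE + dz
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    ]
    for off in offsets:
        lo = np.searchsorted(kf_sorted, ucell + off, side="left")
        hi = np.searchsorted(kf_sorted, ucell + off, side="right")
        cnt1 = hi - lo
        sel = cnt1 > 0
        if not np.any(sel):
            continue
        lo_s, cnt1_s = lo[sel], cnt1[sel]
        start2, cnt2 = ustart[sel], ucount[sel]
        pairs_per_cell = cnt1_s * cnt2
        bounds = np.concatenate([[0], np.cumsum(pairs_per_cell)])
        n_cells = pairs_per_cell.size
        c0 = 0
        while c0 < n_cells:
            # advance whole cells until the chunk budget is filled
            c1 = int(
                np.searchsorted(bounds, bounds[c0] + max_chunk_pairs, side="left")
            )
            c1 = min(max(c1, c0 + 1), n_cells)
            k = np.arange(int(bounds[c1] - bounds[c0]))
            cell_of = np.repeat(np.arange(c0, c1), pairs_per_cell[c0:c1])
            k_local = k - (bounds[c0:c1] - bounds[c0])[cell_of - c0]
            i_idx = lo_s[cell_of] + k_local % cnt1_s[cell_of]
            j_idx = start2[cell_of] + k_local // cnt1_s[cell_of]
            # cheap z-difference test first
            dz_ = np.abs(pf[i_idx, 2] - ps[j_idx, 2])
            keep = dz_ <= tol.eps
            i_idx, j_idx = i_idx[keep], j_idx[keep]
            if i_idx.size:
                d = pf[i_idx] - ps[j_idx]
                keep = np.einsum("ij,ij->i", d, d) <= eps2
                i_idx, j_idx = i_idx[keep], j_idx[keep]
            if i_idx.size:
                # |scalar part of q_first * q_second| = cos(phi/2) of T1 T2
                wrel = np.abs(
                    np.einsum("ij,ij->i", qf[i_idx], qs[j_idx])
                    - 2.0
                    * np.einsum("ij,ij->i", qf[i_idx, 1:], qs[j_idx, 1:])
                )
                ok = wrel >= w_min
                hits += int(np.sum(ok))
                if with_variance and np.any(ok):
                    np.add.at(h_first, i_idx[ok], 1)
                    np.add.at(h_second, j_idx[ok], 1)
            c0 = c1
    if not with_variance:
        return hits
    var = float(
        hits
        + np.sum(h_first * (h_first - 1))
        + np.sum(h_second * (h_second - 1))
    )
    return hits, var


def brute_force_count(
    first: HalfEnsemble,
    second: HalfEnsemble,
    tol: ClosureTolerances,
    chunk: int = 256,
) -> int:
    """All-pairs reference count (O(M^2)); oracle for the binned search."""
    eps2 = tol.eps * tol.eps
    w_min = math.sqrt(max(0.0, 1.0 - tol.delta * tol.delta))
    hits = 0
    for i0 in range(0, first.M, chunk):
        pf = first.end_pos[i0 : i0 + chunk]
        qf = first.end_quat[i0 : i0 + chunk]
        d = pf[:, None, :] - second.end_pos[None, :, :]
        close = np.einsum("ijk,ijk->ij", d, d) <= eps2
        ii, jj = np.nonzero(close)
        if ii.size:
            w1 = qf[ii, 0] * second.end_quat[jj, 0]
            vdot = np.einsum(
                "ij,ij->i", qf[ii, 1:], second.end_quat[jj, 1:]
            )
            hits += int(np.sum(np.abs(w1 - vdot) >= w_min))
    return hits


@dataclass
class JEstimate:
    """A J-factor estimate with its Poisson counting error."""

    J_nM: float
    hits: int
    pairs_total: int
    stderr_log10: float
    is_upper_bound: bool = False

    @property
    def log10J(self) -> float:
        return float(np.log10(self.J_nM)) if self.J_nM > 0 else -np.inf


def estimate_J(
    hits: int, M: int, tol: ClosureTolerances, var_hits: float | None = None
) -> JEstimate:
    """Convert a hit count into a J-factor in nM.

    ``J = hits / (M^2 V_trans V_rot)`` converted from inverse cubic
    angstroms to nM.  The default counting error on log10 J is the Poisson
    ``1/(ln 10 sqrt(hits))``; pass the pair-correlation variance from
    ``pair_and_count(..., with_variance=True)`` as ``var_hits`` for an
    error bar that accounts for halves shared between glued molecules.
    Zero hits yields the one-count upper bound, flagged as such.
    """
    if hits < 0 or M < 1:
        raise ValueError("need hits >= 0 and M >= 1")
    volume = float(M) * float(M) * tol.volume_trans * tol.volume_rot
    if hits == 0:
        return JEstimate(
            NM_PER_INV_CUBIC_ANGSTROM / volume, 0, M * M, np.inf, True
        )
    j = hits / volume * NM_PER_INV_CUBIC_ANGSTROM
    sd = math.sqrt(var_hits) if var_hits is not None else math.sqrt(hits)
    return JEstimate(j, int(hits), M * M, sd / (math.log(10.0) * hits))


def default_split(N: int) -> int:
    """Balanced split frame: m = ceil((N+1)/2)."""
    return (N + 2) // 2


def compute_J(
    spec: MoleculeSpec,
    M: int,
    tol: ClosureTolerances = ClosureTolerances(),
    seed=0,
    split_m: int | None = None,
    grid: BinGrid | None = None,
) -> JEstimate:
    """Generate both half-ensembles for one molecule and estimate J."""
    m = default_split(spec.N) if split_m is None else split_m
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(spec.N, m))
    s_first, s_second = ss.spawn(2)
    first = generate_half_ensemble(
        spec, "first", m, M, np.random.default_rng(s_first)
    )
    second = generate_half_ensemble(
        spec, "second", m, M, np.random.default_rng(s_second)
    )
    hits, var = pair_and_count(first, second, tol, grid, with_variance=True)
    return estimate_J(hits, M, tol, var_hits=var)


def convergence_check(
    spec: MoleculeSpec,
    M: int,
    tol: ClosureTolerances = ClosureTolerances(),
    seed=0,
    split_m: int | None = None,
    n_sigma: float = 3.0,
):
    """Tolerance-resolution check: halve (eps, delta) and compare log10 J.

    In the small-tolerance regime the estimate is a local density average,
    so halving the closure region must leave log10 J unchanged within
    counting error; a shift beyond ``n_sigma`` combined standard errors
    flags tolerances too coarse for the density's curvature.  Returns
    ``(passed, estimate, estimate_halved)``.
    """
    est = compute_J(spec, M, tol, seed=seed, split_m=split_m)
    est_h = compute_J(spec, M, tol.halved(), seed=seed + 1, split_m=split_m)
    if est.is_upper_bound or est_h.is_upper_bound:
        return False, est, est_h
    shift = abs(est.log10J - est_h.log10J)
    limit = n_sigma * math.hypot(est.stderr_log10, est_h.stderr_log10)
    return shift <= limit, est, est_h


class CyclizationProfile:
    """log10 J versus molecule length, one row per basepair length N."""

    columns = ("N", "log10J", "stderr", "hits", "M", "censored")

    def __init__(self, data: pd.DataFrame):
        missing = set(self.columns) - set(data.columns)
        if missing:
            raise ValueError(f"profile table missing columns {sorted(missing)}")
        self.data = data.reset_index(drop=True)

    @property
    def fit_points(self) -> pd.DataFrame:
        """Rows usable for fitting (zero-hit lengths are censored out)."""
        return self.data[~self.data["censored"]]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CyclizationProfile":
        df = pd.read_csv(path)
        if "censored" not in df.columns:
            df["censored"] = False
        for col in ("stderr", "hits", "M"):
            if col not in df.columns:
                df[col] = np.nan
        return cls(df)

    def fit(self, **kwargs):
        """Fit the periodic piecewise-quadratic profile form; see fitting."""
        from .fitting import PeriodicProfileModel

        pts = self.fit_points
        return PeriodicProfileModel(
            pts["N"].to_numpy(), pts["log10J"].to_numpy()
        ).fit(**kwargs)


def cyclization_profile(
    molecule,
    N_values: Iterable[int] = range(146, 171),
    M: int = 1 << 17,
    tol: ClosureTolerances = ClosureTolerances(),
    seed=0,
    split_rule: Callable[[int], int] = default_split,
) -> CyclizationProfile:
    """Compute log10 J over a family of lengths differing by single basepairs.

    ``molecule`` is either a MoleculeSpec (its trailing straight filler is
    resized for each N) or a callable ``N -> MoleculeSpec``.  Each length
    gets an independent seed stream derived from ``seed``, so points are
    statistically independent and individually reproducible.
    """
    factory = molecule if callable(molecule) else molecule.with_length
    rows = []
    for N in N_values:
        spec = factory(int(N))
        est = compute_J(spec, M, tol, seed=seed, split_m=split_rule(int(N)))
        rows.append(
            {
                "N": int(N),
                "log10J": est.log10J if not est.is_upper_bound else np.nan,
                "stderr": est.stderr_log10,
                "hits": est.hits,
                "M": M,
                "censored": est.is_upper_bound,
            }
        )
    return CyclizationProfile(pd.DataFrame(rows))
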