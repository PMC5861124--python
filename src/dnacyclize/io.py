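"""Configs, serialization, synthetic fixtures, and the experiment driver.

Molecule specifications round-trip through plain dictionaries (YAML or JSON
on disk), profiles are CSV tables, fits are JSON objects -- everything
diff-able and tool-agnostic.  ``run_experiment`` ties the pieces together:
it validates a run configuration up front, computes a cyclization profile,
fits it, and writes profile + fit + a reproducibility log atomically.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .elastic import MoleculeSpec, StiffnessSet, stiffness_from_persistence
from .fitting import FitParams, f_periodic, fit_profile
from .geometry import SegmentSpec, frames_from_steps
from .montecarlo import (
    ClosureTolerances,
    CyclizationProfile,
    convergence_check,
    cyclization_profile,
)

__all__ = [
    "spec_to_dict",
    "spec_from_dict",
    "save_molecule_spec",
    "load_molecule_spec",
    "export_shape_csv",
    "generate_profile_fixture",
    "RunConfig",
    "run_experiment",
]


def spec_to_dict(spec: MoleculeSpec) -> dict:
    st = spec.stiffness
    return {
        "segments": [
            {
                "kind": s.kind,
                "n_bp": s.n_bp,
                "bend_total_deg": s.bend_total_deg,
                "pitch_over_circumf": s.pitch_over_circumf,
            }
            for s in spec.segments
        ],
        "N": spec.N,
        "helical_repeat": spec.helical_repeat,
        "ell": spec.ell,
        "stiffness": {
            "K1_RT": st.K1,
            "K2_over_K1": st.K2 / st.K1,
            "K3_over_K1": st.K3 / st.K1,
            "A_RT_per_A2": [st.A1, st.A2, st.A3],
            "scale_beta": st.scale_beta,
            "extensible": st.extensible,
        },
    }


def _stiffness_from_dict(d: dict) -> StiffnessSet:
    d = dict(d)
    if "persistence_nm" in d and "K1_RT" in d:
        raise ValueError("stiffness: give persistence_nm or K1_RT, not both")
    if "persistence_nm" in d:
        k1 = stiffness_from_persistence(float(d.pop("persistence_nm")))
    else:
        k1 = float(d.pop("K1_RT", stiffness_from_persistence(46.3)))
    k2 = k1 * float(d.pop("K2_over_K1", 1.0))
    k3 = k1 * float(d.pop("K3_over_K1", 1.5))
    a = d.pop("A_RT_per_A2", list(StiffnessSet().effective()[1]))
    if len(a) != 3:
        raise ValueError("stiffness: A_RT_per_A2 needs three values")
    out = StiffnessSet(
        K1=k1,
        K2=k2,
        K3=k3,
        A1=float(a[0]),
        A2=float(a[1]),
        A3=float(a[2]),
        scale_beta=float(d.pop("scale_beta", 1.0)),
        extensible=bool(d.pop("extensible", True)),
    )
    if d:
        raise ValueError(f"stiffness: unknown fields {sorted(d)}")
    return out


def spec_from_dict(d: dict) -> MoleculeSpec:
    d = dict(d)
    try:
        segments = [
            SegmentSpec(
                kind=s["kind"],
                n_bp=int(s["n_bp"]),
                bend_total_deg=float(s.get("bend_total_deg", 0.0)),
                pitch_over_circumf=float(s.get("pitch_over_circumf", 0.0)),
            )
            for s in d.pop("segments", [])
        ]
        N = int(d.pop("N"))
    except KeyError as exc:
        raise ValueError(f"molecule spec: missing field {exc.args[0]!r}") from None
    spec = MoleculeSpec(
        segments=segments,
        N=N,
        helical_repeat=float(d.pop("helical_repeat", 10.5)),
        stiffness=_stiffness_from_dict(d.pop("stiffness", {})),
        ell=float(d.pop("ell", 3.4)),
    )
    if d:
        raise ValueError(f"molecule spec: unknown fields {sorted(d)}")
    return spec


def save_molecule_spec(spec: MoleculeSpec, path) -> None:
    path = Path(path)
    data = spec_to_dict(spec)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_molecule_spec(path) -> MoleculeSpec:
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return spec_from_dict(data)


def export_shape_csv(spec: MoleculeSpec, path) -> pd.DataFrame:
    """Write the intrinsic shape as per-frame origins and tangents."""
    theta, trans = spec.intrinsic_shape()
    origins, quats = frames_from_steps(theta, trans)
    from ._quat import quat_to_matrix

    d3 = quat_to_matrix(quats)[:, :, 2]
    df = pd.DataFrame(
        {
            "i": np.arange(1, origins.shape[0] + 1),
            "x": origins[:, 0],
            "y": origins[:, 1],
            "z": origins[:, 2],
            "d3x": d3[:, 0],
            "d3y": d3[:, 1],
            "d3z": d3[:, 2],
        }
    )
    df.to_csv(path, index=False)
    return df


def generate_profile_fixture(
    params: FitParams,
    N_range=range(146, 171),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic profile from the periodic form plus Gaussian noise.

    Lets the fitting layer be exercised (and its error calibrated) without
    running any Monte Carlo.  Deterministic for a given seed; sigma = 0
    returns the exact model values.
    """
    N = np.asarray(list(N_range), dtype=float)
    y = (
        params.a
        + params.b * (N - params.phi)
        + params.c * f_periodic(N, params.phi, params.p) ** 2
    )
    if noise_sigma:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sigma, size=N.size)
    return pd.DataFrame({"N": N.astype(int), "log10J": y})


@dataclass
class RunConfig:
    """Validated inputs of one profile experiment."""

    molecule: MoleculeSpec
    N_range: tuple[int, int] = (146, 170)
    M: int = 1 << 17
    eps: float = 30.0
    delta: float = 0.3
    seed: int = 0
    out_profile: str = "profile.csv"
    out_fit: str | None = None
    out_log: str | None = None
    check_convergence: bool = False

    def __post_init__(self):
        lo, hi = self.N_range
        if not (2 <= lo <= hi):
            raise ValueError("N_range: need 2 <= first <= last")
        if self.M < 1:
            raise ValueError("M: must be a positive sample count")
        self.tol = ClosureTolerances(self.eps, self.delta)  # validates both

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "molecule" not in d:
            raise ValueError("config: missing field 'molecule'")
        mol = d.pop("molecule")
        if isinstance(mol, str):
            mol = load_molecule_spec(mol)
        else:
            mol = dict(mol)
            mol.setdefault("N", d.get("N_range", [146, 170])[1])
            mol = spec_from_dict(mol)
        known = {
            "N_range",
            "M",
            "eps",
            "delta",
            "seed",
            "out_profile",
            "out_fit",
            "out_log",
            "check_convergence",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"config: unknown fields {sorted(unknown)}")
        if "N_range" in d:
            d["N_range"] = tuple(int(v) for v in d["N_range"])
        return cls(molecule=mol, **d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)


def _atomic_write(path: Path, writer) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def run_experiment(config: RunConfig) -> dict:
    """Compute a profile, fit it, and write all artifacts atomically.

    Returns a dict with the profile, the fit results (or None when too few
    points survive censoring), and the log record.
    """
    lo, hi = config.N_range
    profile = cyclization_profile(
        config.molecule,
        range(lo, hi + 1),
        M=config.M,
        tol=config.tol,
        seed=config.seed,
    )
    _atomic_write(Path(config.out_profile), profile.to_csv)

    fit = None
    if profile.fit_points.shape[0] >= 10:
        fit = profile.fit()
        if config.out_fit:
            payload = dict(fit.params)
            payload["rss"] = fit.rss
            _atomic_write(
                Path(config.out_fit),
                lambda p: p.write_text(json.dumps(payload, indent=2)),
            )

    log = {
        "config": {
            "N_range": list(config.N_range),
            "M": config.M,
            "eps": config.eps,
            "delta": config.delta,
            "seed": config.seed,
        },
        "molecule": spec_to_dict(config.molecule),
        "hits": dict(zip(profile.data["N"].astype(int), profile.data["hits"].astype(int))),
        "censored": profile.data.loc[profile.data["censored"], "N"].astype(int).tolist(),
    }
    if config.check_convergence:
        mid = (lo + hi) // 2
        ok, est, est_h = convergence_check(
            config.molecule.with_length(mid), config.M, config.tol, seed=config.seed
        )
        log["convergence_check"] = {
            "N": mid,
            "passed": bool(ok),
            "log10J": est.log10J,
            "log10J_halved_tol": est_h.log10J,
        }
        if not ok:
            log["warnings"] = [
                "tolerance-halving check failed: closure tolerances too coarse "
                "for the end-state density at this length"
            ]
    if config.out_log:
        _atomic_write(
            Path(config.out_log),
            lambda p: p.write_text(json.dumps(log, indent=2)),
        )
    return {"profile": profile, "fit": fit, "log": log}
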