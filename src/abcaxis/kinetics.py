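"""Michaelis-Menten fitting of ATPase rate data.

Transporter ATPase activity v (nmol phosphate released / min / mg protein)
measured as a function of MgATP concentration S (mM) is fit to

    v = V_max * S / (K_m + S)

by unweighted nonlinear least squares, per condition (detergent vs nanodisc
solubilization; with or without glutathione substrate).  Replicates enter as
individual points.  Initialization is data-driven and reproducible:
V_max0 = max(v), K_m0 = S at half-maximal v by interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError

SOLUBILIZATIONS = ("DDM", "nanodisc")
SUBSTRATES = ("none", "GSSG 2.5 mM", "GSH 10 mM")


@dataclass
class KineticsDataset:
    """(S, v) points for one condition; replicates allowed."""

    solubilization: str
    substrate: str
    s: np.ndarray   # mM MgATP
    v: np.ndarray   # nmol/min/mg

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.s.shape != self.v.shape:
            raise ValueError("S and v must have the same length")
        if np.any(self.s < 0):
            raise ValueError("substrate concentrations must be >= 0")

    @property
    def condition(self) -> str:
        return f"{self.solubilization}:{self.substrate}"

    @property
    def n_distinct_s(self) -> int:
        return len(np.unique(self.s))


@dataclass
class MMFit:
    """Fitted Michaelis-Menten parameters and diagnostics."""

    v_max: float        # nmol/min/mg
    k_m: float          # mM
    v_max_se: float
    k_m_se: float
    rss: float
    n_points: int
    condition: str = ""

    def predict(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return self.v_max * s / (self.k_m + s)


def michaelis_menten(s: np.ndarray, v_max: float, k_m: float) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    return v_max * s / (k_m + s)


def _default_init(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """V_max0 = max(v); K_m0 = S at half-max by interpolation of S-mean rates."""
    order = np.argsort(s)
    s_sorted, v_sorted = s[order], v[order]
    # average replicates per S for a monotone-ish interpolation target
    su, inv = np.unique(s_sorted, return_inverse=True)
    vu = np.bincount(inv, weights=v_sorted) / np.bincount(inv)
    v0 = float(np.max(v))
    half = v0 / 2.0
    above = np.nonzero(vu >= half)[0]
    if len(above) == 0 or above[0] == 0:
        k0 = float(su[len(su) // 2]) or 0.1
    else:
        i = above[0]
        s_lo, s_hi = su[i - 1], su[i]
        v_lo, v_hi = vu[i - 1], vu[i]
        frac = (half - v_lo) / (v_hi - v_lo) if v_hi != v_lo else 0.5
        k0 = float(s_lo + frac * (s_hi - s_lo))
    return v0, max(k0, 1e-6)


def fit_michaelis_menten(data: KineticsDataset,
                         init: tuple[float, float] | None = None) -> MMFit:
    """Unweighted nonlinear least-squares Michaelis-Menten fit.

    Raises :class:`FitError` on non-convergence; a non-positive parameter at
    the optimum raises as a boundary failure (the model is only meaningful
    with V_max, K_m > 0).
    """
    s, v = data.s, data.v
    if data.n_distinct_s < 4:
        raise FitError(
            f"need >= 4 distinct substrate concentrations; got {data.n_distinct_s}")
    p0 = init if init is not None else _default_init(s, v)
    # fit on rate-normalized data so the optimization (and therefore the
    # result) is exactly equivariant under rescaling of v
    scale = float(np.max(np.abs(v)))
    if scale <= 0:
        raise FitError(f"all rates are zero for {data.condition}")
    try:
        popt, pcov = curve_fit(michaelis_menten, s, v / scale,
                               p0=(p0[0] / scale, p0[1]), maxfev=10000,
                               xtol=1e-12, ftol=1e-12, gtol=1e-12)
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit did not converge for "
                       f"{data.condition}: {exc}") from exc
    pcov = pcov * np.array([[scale * scale, scale], [scale, 1.0]])
    v_max, k_m = float(popt[0]) * scale, float(popt[1])
    if v_max <= 0 or k_m <= 0:
        raise FitError(
            f"fit for {data.condition} hit a non-positive parameter "
            f"(V_max={v_max:.4g}, K_m={k_m:.4g})")
    resid = v - michaelis_menten(s, v_max, k_m)
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else (np.nan, np.nan)
    return MMFit(v_max=v_max, k_m=k_m, v_max_se=float(se[0]), k_m_se=float(se[1]),
                 rss=float(np.sum(resid ** 2)), n_points=len(s),
                 condition=data.condition)


def read_kinetics_table(path: str | Path) -> list[KineticsDataset]:
    """Read a (solubilization, substrate, S, v) CSV/TSV into datasets.

    The delimiter is sniffed from the extension ('.csv' vs anything else =
    tab).  Column names are matched case-insensitively; ``condition`` in the
    form 'DDM:none' may replace the two label columns.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    if "condition" in df.columns:
        parts = df["condition"].str.split(":", n=1, expand=True)
        df["solubilization"] = parts[0]
        df["substrate"] = parts[1].fillna("none")
    for col in ("solubilization", "substrate", "s", "v"):
        if col not in df.columns:
            raise FitError(f"kinetics table {path} lacks column {col!r}")
    out = []
    for (sol, sub), grp in df.groupby(["solubilization", "substrate"], sort=False):
        out.append(KineticsDataset(solubilization=str(sol), substrate=str(sub),
                                   s=grp["s"].to_numpy(), v=grp["v"].to_numpy()))
    return out


def write_kinetics_table(datasets: list[KineticsDataset], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for d in datasets:
        for s, v in zip(d.s, d.v):
            rows.append({"solubilization": d.solubilization, "substrate": d.substrate,
                         "s": s, "v": v})
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
    return path
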