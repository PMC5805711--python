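"""Single-site binding analysis of NMR titration CSPs.

For a protein P titrated with ligand L in fast exchange, the observed
CSP of each residue follows the exact single-site isotherm

    Δδ = Δδ_max · { [P]t + [L]t + Kd − sqrt(([P]t+[L]t+Kd)² − 4[P]t[L]t) } / (2[P]t)

i.e. Δδ_max times the bound fraction from the quadratic mass balance.
:func:`global_kd_fit` fits all residues of a titration jointly with one
shared Kd and a per-residue Δδ_max.  Residues in intermediate/slow
exchange do not trace this curve — their signals attenuate instead — and
are detected by :func:`attenuation_classify` and excluded from the fit.

:func:`alt_depletion` tracks how a slow-exchange alternate conformer is
drained by ligand binding to the binding-competent native conformer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Minimizer, Parameters

from .csp import combined_csp
from .equilibrium import FitError
from .peakdata import Conformer, Site, TitrationSeries

__all__ = [
    "BindingPoint",
    "BindingFitResult",
    "binding_isotherm",
    "bound_fraction",
    "global_kd_fit",
    "attenuation_classify",
    "alt_depletion",
]


@dataclass(frozen=True)
class BindingPoint:
    """One titration point: totals plus per-residue observables."""

    protein_total: float  # molar
    ligand_total: float   # molar
    csp: dict[int, float] = field(default_factory=dict)        # residue -> ppm
    rel_intensity: dict[int, float] = field(default_factory=dict)  # residue -> I/I0

    def __post_init__(self) -> None:
        if self.protein_total < 0 or self.ligand_total < 0:
            raise ValueError("concentrations must be >= 0")


@dataclass
class BindingFitResult:
    """Global shared-Kd fit over residues and titration points."""

    kd: float                       # molar
    dmax: dict[int, float]          # residue -> ppm
    se_kd: float
    se_dmax: dict[int, float]
    residues_used: list[int]
    residues_excluded: list[int]
    n_points: int


def bound_fraction(P_t, L_t, Kd):
    """Bound-protein fraction [PL]/[P]t from the quadratic mass balance.

    Evaluated via the numerically stable root form
    [PL] = 2·[P]t·[L]t / (S + sqrt(S² − 4·[P]t·[L]t)), S = [P]t+[L]t+Kd,
    which avoids the catastrophic cancellation of the textbook
    (S − sqrt(...))/2 expression when [PL] ≪ S.
    """
    P_t = np.asarray(P_t, dtype=float)
    L_t = np.asarray(L_t, dtype=float)
    if np.any(P_t <= 0):
        raise ValueError("protein_total must be > 0")
    if np.any(L_t < 0) or Kd < 0:
        raise ValueError("ligand_total and Kd must be >= 0")
    S = P_t + L_t + Kd
    disc = np.maximum(S * S - 4.0 * P_t * L_t, 0.0)
    denom = S + np.sqrt(disc)
    complex_conc = np.where(denom > 0, 2.0 * P_t * L_t / np.where(denom > 0, denom, 1.0), 0.0)
    return complex_conc / P_t


def binding_isotherm(P_t, L_t, Kd, dmax):
    """Observed fast-exchange CSP Δδ = Δδ_max · bound fraction (ppm)."""
    return dmax * bound_fraction(P_t, L_t, Kd)


def global_kd_fit(
    points: list[BindingPoint],
    residues: set[int] | None = None,
    kd_guess: float | None = None,
) -> BindingFitResult:
    """Fit one shared Kd and per-residue Δδ_max to a whole titration.

    Minimizes the summed squared residuals of the single-site isotherm
    over every (residue, titration point) pair by trust-region least
    squares; standard errors come from the Jacobian at the optimum.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 titration points")
    available = sorted(set().union(*(p.csp.keys() for p in points)))
    use = [r for r in available if residues is None or r in residues]
    if not use:
        raise ValueError("no residues to fit (all excluded?)")

    rows = []  # (residue, P_t, L_t, csp)
    for p in points:
        for r in use:
            if r in p.csp:
                rows.append((r, p.protein_total, p.ligand_total, p.csp[r]))
    data = pd.DataFrame(rows, columns=["residue", "P_t", "L_t", "csp"])

    if kd_guess is None:
        kd_guess = float(np.median(data["P_t"]))
    params = Parameters()
    params.add("kd", value=kd_guess, min=1e-12)
    for r in use:
        dmax0 = float(data.loc[data["residue"] == r, "csp"].max())
        params.add(f"dmax_{r}", value=max(dmax0, 1e-6), min=0.0)

    res_idx = data["residue"].to_numpy()
    P = data["P_t"].to_numpy()
    L = data["L_t"].to_numpy()
    obs = data["csp"].to_numpy()

    def residual(pars):
        kd = pars["kd"].value
        fb = bound_fraction(P, L, kd)
        dmax = np.array([pars[f"dmax_{r}"].value for r in res_idx])
        return dmax * fb - obs

    out = Minimizer(residual, params).least_squares()
    if not out.success:
        raise FitError(f"global Kd fit did not converge: {out.message}")
    p = out.params
    kd = float(p["kd"].value)
    se_kd = float(p["kd"].stderr) if p["kd"].stderr is not None else float("nan")
    dmax = {r: float(p[f"dmax_{r}"].value) for r in use}
    se_dmax = {
        r: (float(p[f"dmax_{r}"].stderr) if p[f"dmax_{r}"].stderr is not None else float("nan"))
        for r in use
    }
    return BindingFitResult(
        kd=kd,
        dmax=dmax,
        se_kd=se_kd,
        se_dmax=se_dmax,
        residues_used=use,
        residues_excluded=[r for r in available if r not in use],
        n_points=len(points),
    )


def attenuation_classify(
    series: TitrationSeries,
    threshold: float = 0.75,
    conformer: Conformer = Conformer.NAT,
) -> dict[int, bool]:
    """Flag residues whose signal attenuates by more than ``threshold``.

    Compares each residue's backbone-amide intensity at the final
    titration point with the first: flagged when
    I_end < (1 − threshold)·I_start, the signature of intermediate/slow
    exchange at a binding interface.  Flagged residues should be
    excluded from the fast-exchange CSP fit.
    """
    first, last = series.points[0], series.points[-1]
    flags: dict[int, bool] = {}
    for peak in first:
        if peak.site is not Site.BACKBONE or peak.conformer is not conformer:
            continue
        end = last.get(peak.residue_index, peak.site, peak.conformer)
        if peak.intensity == 0:
            continue
        end_intensity = end.intensity if end is not None else 0.0
        flags[peak.residue_index] = bool(end_intensity < (1.0 - threshold) * peak.intensity)
    return flags


def binding_points_from_series(
    series: TitrationSeries,
    scale_N: float = 5.0,
    exclude_attenuated: bool = True,
    attenuation_threshold: float = 0.75,
) -> tuple[list[BindingPoint], list[int]]:
    """Convert a ligand titration into :class:`BindingPoint` rows.

    CSPs are measured for native-conformer backbone amides against the
    first (ligand-free) point.  When ``exclude_attenuated`` is set,
    residues flagged by :func:`attenuation_classify` are dropped from
    the CSP tables (returned separately) — the default analysis path.
    """
    if series.varying != "ligand":
        raise ValueError("series must vary ligand concentration")
    flags = attenuation_classify(series, attenuation_threshold)
    attenuated = sorted(r for r, f in flags.items() if f)
    ref = series.points[0]
    pts: list[BindingPoint] = []
    for pl in series:
        cond = pl.condition
        if cond.protein_total is None or cond.ligand_total is None:
            raise ValueError(f"point {pl.label!r} lacks protein/ligand totals")
        csp: dict[int, float] = {}
        rel: dict[int, float] = {}
        for peak in ref:
            if peak.site is not Site.BACKBONE or peak.conformer is not Conformer.NAT:
                continue
            cur = pl.get(peak.residue_index, peak.site, peak.conformer)
            if cur is None:
                continue
            r = peak.residue_index
            if peak.intensity > 0:
                rel[r] = cur.intensity / peak.intensity
            if exclude_attenuated and r in attenuated:
                continue
            csp[r] = combined_csp(cur.shift_H - peak.shift_H, cur.shift_N - peak.shift_N,
                                  scale_N)
        pts.append(BindingPoint(cond.protein_total, cond.ligand_total, csp, rel))
    return pts, attenuated


def alt_depletion(
    series: TitrationSeries,
    residues: set[int] | None = None,
) -> pd.DataFrame:
    """Residue-averaged alternate-conformer population along a ligand series.

    Returns a frame indexed by ligand equivalents ([L]t/[P]t) with
    columns ``f_alt`` (mean over residues), ``sd`` and ``n``; the
    ``attrs['monotone_decreasing']`` flag reports whether the mean
    strictly decreases with added ligand.
    """
    from .equilibrium import fraction_alt

    rows = []
    for pl in series:
        cond = pl.condition
        if cond.protein_total in (None, 0) or cond.ligand_total is None:
            raise ValueError(f"point {pl.label!r} lacks protein/ligand totals")
        recs, mean, sd = fraction_alt(pl, residues)
        rows.append(
            {"equivalents": cond.ligand_total / cond.protein_total,
             "f_alt": mean, "sd": sd, "n": len(recs)}
        )
    df = pd.DataFrame(rows).set_index("equivalents").sort_index()
    f = df["f_alt"].to_numpy()
    df.attrs["monotone_decreasing"] = bool(np.all(np.diff(f) < 0)) if len(f) > 1 else False
    if df["n"].eq(0).any():
        warnings.warn("some points have no residues with both conformers", stacklevel=2)
    return df
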