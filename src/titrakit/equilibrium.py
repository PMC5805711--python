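"""Two-state conformer population statistics and their model fits.

For a protein whose two conformers are in slow exchange, each residue
shows two resolved amide peaks whose intensities are proportional to the
conformer populations, so

    f_alt = I_alt / (I_nat + I_alt)

measures the population of the alternate state directly (valid when the
transverse relaxation rates of the two signal sets match, so intensities
are comparable).

Two models connect these populations to physics:

*   van't Hoff:  ln(I_alt/I_nat) = −ΔH/(RT) + ΔS/R  — a line in 1/T whose
    slope and intercept give the enthalpy and entropy of the equilibrium.
*   acid–base:   f_alt(pH) = offset + scale·θ(pH) with
    θ = 10^(pH−pKa) / (1 + 10^(pH−pKa)) — the Henderson–Hasselbalch
    population of the deprotonated species.  The saturating θ is the
    default; the unbounded literal form θ = 10^(pH−pKa) is kept behind
    ``mode="literal"`` for comparison (it cannot produce a sigmoid and is
    only identifiable up to scale·10^−pKa, so its amplitude is held fixed
    at the data range).

The same acid–base model, with the normalized titration CSP in place of
f_alt, yields per-residue pKa values from fast-exchange peak movement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model

from .csp import normalized_csp
from .peakdata import Conformer, PeakList, Site, TitrationSeries, Trajectory

__all__ = [
    "R_GAS",
    "FractionRecord",
    "VantHoffResult",
    "PkaFitResult",
    "fraction_alt",
    "fraction_alt_series",
    "vant_hoff_fit",
    "ph_population_fit",
    "csp_pka_fit",
]

#: gas constant, J/(mol*K)
R_GAS = 8.314


class FitError(RuntimeError):
    """A model fit failed to converge or was ill-posed."""


@dataclass(frozen=True)
class FractionRecord:
    """Alternate-conformer population of one residue at one condition."""

    residue_index: int
    condition_value: float  # pH (dimensionless) or temperature (K)
    f_alt: float
    ln_ratio: float  # ln(I_alt / I_nat); -inf when I_alt == 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_alt <= 1.0):
            raise ValueError(f"f_alt must be in [0, 1], got {self.f_alt}")


@dataclass
class VantHoffResult:
    """Linear van't Hoff fit of ln(I_alt/I_nat) on 1/T."""

    delta_H: float  # J/mol
    delta_S: float  # J/(mol*K)
    covariance: np.ndarray  # 2x2 covariance of (delta_H, delta_S)
    n_points: int

    @property
    def se_delta_H(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    @property
    def se_delta_S(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))

    def delta_G(self, temperature: float = 298.15) -> float:
        """ΔG(T) = ΔH − T·ΔS, J/mol."""
        return self.delta_H - temperature * self.delta_S

    def se_delta_G(self, temperature: float = 298.15) -> float:
        """Standard error of ΔG(T) propagated with the (ΔH, ΔS) covariance.

        ΔH and ΔS from one regression are strongly correlated, so the
        cross term dominates; ignoring it overestimates the ΔG error by
        an order of magnitude.
        """
        t = temperature
        var = (
            self.covariance[0, 0]
            + t * t * self.covariance[1, 1]
            - 2 * t * self.covariance[0, 1]
        )
        return float(np.sqrt(max(var, 0.0)))

    def ratio(self, temperature: float = 298.15) -> float:
        """Implied I_alt/I_nat = exp(−ΔG/RT) at a temperature."""
        return math.exp(-self.delta_G(temperature) / (R_GAS * temperature))


@dataclass
class PkaFitResult:
    """Acid–base titration fit: value = offset + amplitude·θ(pH)."""

    pKa: float
    offset: float
    amplitude: float
    se_pKa: float = float("nan")
    se_offset: float = float("nan")
    se_amplitude: float = float("nan")
    mode: str = "saturating"
    rejected: bool = False
    per_residue_pka: dict[int, float] = field(default_factory=dict)

    @property
    def pka_spread(self) -> tuple[float, float] | None:
        if not self.per_residue_pka:
            return None
        vals = list(self.per_residue_pka.values())
        return (min(vals), max(vals))

    def predict(self, pH: np.ndarray | float) -> np.ndarray | float:
        return _pka_model(np.asarray(pH, dtype=float), self.offset, self.amplitude,
                          self.pKa, self.mode)


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

def fraction_alt(
    peaklist: PeakList,
    residues: set[int] | None = None,
) -> tuple[list[FractionRecord], float, float]:
    """Per-residue f_alt = I_alt/(I_nat + I_alt) plus mean ± sd across residues.

    Uses backbone-amide peaks only; residues lacking either conformer
    are ignored, residues whose total intensity is zero are skipped with
    a warning.
    """
    cond = peaklist.condition
    value = cond.pH if cond.pH is not None else (cond.temperature or float("nan"))
    records: list[FractionRecord] = []
    candidates = sorted(residues) if residues is not None else sorted(peaklist.residues)
    for r in candidates:
        nat = peaklist.get(r, Site.BACKBONE, Conformer.NAT)
        alt = peaklist.get(r, Site.BACKBONE, Conformer.ALT)
        if nat is None or alt is None:
            continue
        total = nat.intensity + alt.intensity
        if total == 0:
            warnings.warn(f"residue {r}: zero total intensity, f_alt undefined", stacklevel=2)
            continue
        f = alt.intensity / total
        ln_ratio = math.log(alt.intensity / nat.intensity) if alt.intensity > 0 and nat.intensity > 0 else -math.inf
        records.append(FractionRecord(r, value, f, ln_ratio))
    fs = [rec.f_alt for rec in records]
    mean = float(np.mean(fs)) if fs else float("nan")
    sd = float(np.std(fs, ddof=1)) if len(fs) > 1 else float("nan")
    return records, mean, sd


def fraction_alt_series(
    series: TitrationSeries,
    residues: set[int] | None = None,
) -> list[FractionRecord]:
    """f_alt records for every residue at every point of a series."""
    out: list[FractionRecord] = []
    for peaklist in series:
        value = peaklist.condition.value_of(series.varying)
        recs, _, _ = fraction_alt(peaklist, residues)
        out.extend(
            FractionRecord(r.residue_index, value, r.f_alt, r.ln_ratio) for r in recs
        )
    return out


# ---------------------------------------------------------------------------
# van't Hoff
# ---------------------------------------------------------------------------

def vant_hoff_fit(records: list[FractionRecord]) -> VantHoffResult:
    """Ordinary least squares of ln(I_alt/I_nat) on 1/T.

    Slope = −ΔH/R and intercept = ΔS/R.  Requires at least two distinct
    temperatures and strictly positive intensity ratios; with exactly
    two points the fit is the closed-form line through them (covariance
    undefined).  Parameter uncertainties come from the regression
    covariance of (slope, intercept).
    """
    if not records:
        raise ValueError("no records")
    for rec in records:
        if not np.isfinite(rec.ln_ratio):
            raise ValueError(
                f"nonpositive intensity ratio at T={rec.condition_value} K "
                f"(residue {rec.residue_index}); van't Hoff fit needs I_alt, I_nat > 0"
            )
    T = np.array([rec.condition_value for rec in records], dtype=float)
    y = np.array([rec.ln_ratio for rec in records], dtype=float)
    if len(np.unique(T)) < 2:
        raise ValueError("need at least two distinct temperatures")
    X = np.column_stack([1.0 / T, np.ones_like(T)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    slope, intercept = beta
    resid = y - X @ beta
    dof = len(y) - 2
    if dof > 0:
        s2 = float(resid @ resid) / dof
        cov_beta = s2 * np.linalg.inv(X.T @ X)
    else:
        cov_beta = np.full((2, 2), np.nan)
    delta_H = -R_GAS * slope
    delta_S = R_GAS * intercept
    # (dH, dS) = (-R*b0, R*b1): propagate the regression covariance
    J = np.array([[-R_GAS, 0.0], [0.0, R_GAS]])
    cov = J @ cov_beta @ J.T
    return VantHoffResult(float(delta_H), float(delta_S), cov, n_points=len(y))


# ---------------------------------------------------------------------------
# pKa fitting
# ---------------------------------------------------------------------------

def _theta(pH: np.ndarray, pKa: float, mode: str) -> np.ndarray:
    x = np.power(10.0, pH - pKa)
    if mode == "saturating":
        return x / (1.0 + x)
    if mode == "literal":
        return x
    raise ValueError(f"unknown mode {mode!r}")


def _pka_model(pH: np.ndarray, offset: float, amplitude: float, pKa: float,
               mode: str = "saturating") -> np.ndarray:
    return offset + amplitude * _theta(pH, pKa, mode)


def _initial_guess(pH: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    order = np.argsort(pH)
    pH, y = pH[order], y[order]
    dy = np.diff(y)
    dx = np.diff(pH)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(dx != 0, dy / dx, 0.0)
    k = int(np.argmax(np.abs(slope)))
    pKa0 = 0.5 * (pH[k] + pH[k + 1])
    offset0 = float(np.min(y))
    scale0 = float(np.max(y) - np.min(y))
    return pKa0, offset0, scale0


def _fit_pka_curve(pH: np.ndarray, y: np.ndarray, mode: str,
                   weights: np.ndarray | None = None,
                   min_amplitude: float = 1e-9) -> PkaFitResult:
    pH = np.asarray(pH, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(pH) < 4:
        raise ValueError("need at least 4 pH points spanning the transition")
    pKa0, offset0, scale0 = _initial_guess(pH, y)
    if scale0 < min_amplitude:
        warnings.warn("flat titration curve: amplitude ~ 0, fit rejected", stacklevel=3)
        return PkaFitResult(float("nan"), float(np.mean(y)), 0.0, mode=mode, rejected=True)
    def curve(pH, offset, amplitude, pKa):
        return _pka_model(pH, offset, amplitude, pKa, mode)

    model = Model(curve, independent_vars=["pH"])
    params = model.make_params(offset=offset0, amplitude=scale0, pKa=pKa0)
    params["pKa"].set(min=float(pH.min()) - 1.0, max=float(pH.max()) + 1.0)
    if mode == "literal":
        # offset + A*10^(pH-pKa) is degenerate in (A, pKa): hold A at the
        # data-range estimate and fit (offset, pKa) only.
        params["amplitude"].set(vary=False)
    result = model.fit(y, params, pH=pH, weights=weights)
    if not result.success:
        raise FitError(f"pKa fit did not converge; final residuals {result.residual}")
    p = result.params
    out = PkaFitResult(
        pKa=float(p["pKa"].value),
        offset=float(p["offset"].value),
        amplitude=float(p["amplitude"].value),
        se_pKa=float(p["pKa"].stderr) if p["pKa"].stderr is not None else float("nan"),
        se_offset=float(p["offset"].stderr) if p["offset"].stderr is not None else float("nan"),
        se_amplitude=(
            float(p["amplitude"].stderr) if p["amplitude"].stderr is not None else float("nan")
        ),
        mode=mode,
    )
    if not (pH.min() <= out.pKa <= pH.max()):
        warnings.warn(
            f"fitted pKa {out.pKa:.2f} lies outside the sampled pH range "
            f"[{pH.min():.1f}, {pH.max():.1f}]",
            stacklevel=3,
        )
    return out


def ph_population_fit(
    records: list[FractionRecord],
    mode: str = "saturating",
    per_residue: bool = True,
) -> PkaFitResult:
    """Fit f_alt(pH) = offset + scale·θ(pH) to conformer populations.

    The headline parameters come from a fit to the residue-averaged
    curve; with ``per_residue`` (and at least four pH points per
    residue) each residue is also fit individually and the per-residue
    pKa values and their spread are reported alongside.
    """
    if not records:
        raise ValueError("no records")
    df = pd.DataFrame(
        {
            "residue": [r.residue_index for r in records],
            "pH": [r.condition_value for r in records],
            "f_alt": [r.f_alt for r in records],
        }
    )
    mean_curve = df.groupby("pH")["f_alt"].mean()
    result = _fit_pka_curve(mean_curve.index.to_numpy(), mean_curve.to_numpy(), mode)
    if per_residue and df["residue"].nunique() > 1:
        for res, sub in df.groupby("residue"):
            if len(sub) < 4:
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r = _fit_pka_curve(sub["pH"].to_numpy(), sub["f_alt"].to_numpy(), mode)
            except (FitError, ValueError):
                continue
            if not r.rejected:
                result.per_residue_pka[int(res)] = r.pKa
    return result


def csp_pka_fit(
    trajectories: dict[tuple, Trajectory] | dict[int, pd.Series],
    mode: str = "saturating",
    baseline_pH: float = 4.8,
    reference_pH: float = 7.6,
) -> dict[int, PkaFitResult]:
    """Per-residue pKa fits of normalized titration CSPs.

    Accepts either raw trajectories from :func:`titrakit.peakdata.track_peaks`
    (normalized internally against ``baseline_pH`` / ``reference_pH``) or
    pre-normalized per-residue ``pandas.Series`` indexed by pH.  Residues
    whose signal does not move (flat curve) are rejected with a warning
    and returned with ``rejected=True``.
    """
    out: dict[int, PkaFitResult] = {}
    for key, traj in trajectories.items():
        if isinstance(traj, Trajectory):
            residue = traj.residue_index
            try:
                series = normalized_csp(traj, baseline_pH, reference_pH)
            except ZeroDivisionError:
                warnings.warn(f"residue {residue}: stationary signal, pKa fit rejected",
                              stacklevel=2)
                out[residue] = PkaFitResult(float("nan"), 0.0, 0.0, mode=mode, rejected=True)
                continue
        else:
            residue = int(key)
            series = traj
        out[residue] = _fit_pka_curve(series.index.to_numpy(), series.to_numpy(), mode)
    return out
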