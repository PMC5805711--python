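"""Seeded generator of synthetic titration peak lists and rate tables.

Emulates the NMR observables of a two-state slow-exchange protein such
as S65-phosphorylated ubiquitin:

* two conformer signal sets (``nat``/``alt``) whose intensity split
  follows an acid–base population model (pKa near 7) and a Boltzmann
  temperature model (ΔH, ΔS);
* fast-exchange pH-dependent peak movement per residue along linear
  trajectories (per-residue pKa and limiting shift);
* fast-exchange binding trajectories following the exact single-site
  isotherm, with planted interface residues that attenuate instead
  (intermediate exchange) and alternate-conformer depletion coupled to
  the bound fraction;
* Gaussian shift noise and multiplicative intensity noise.

All randomness is split into a *layout* stream (peak positions,
per-residue parameters — fixed by ``layout_seed`` so different noise
seeds share an identical noise-free core) and a *noise* stream derived
from the run seed.  Every generated series passes
:mod:`titrakit.peakdata` validation and carries the ground truth needed
to check parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .binding import bound_fraction
from .equilibrium import R_GAS
from .peakdata import Condition, Conformer, Peak, PeakList, Site, TitrationSeries
from .relaxation import DIMER_FACTOR, RelaxationRecord

__all__ = ["GroundTruth", "gen_ph_series", "gen_temperature_series",
           "gen_binding_series", "gen_relaxation", "UBIQUITIN_SEQUENCE"]

#: human ubiquitin, 1-letter codes, residues 1-76
UBIQUITIN_SEQUENCE = "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYNIQKESTLHLVLRLRGG"

_PROLINES = {19, 37, 38}  # no backbone amide


def _default_residues() -> list[int]:
    # observable backbone amides: skip N-terminus and prolines
    return [i for i in range(2, 77) if i not in _PROLINES]


@dataclass
class GroundTruth:
    """All parameters of the forward models, plus the noise model.

    Defaults emulate the phosphorylated-ubiquitin study conditions:
    conformer equilibrium with pKa 7.08 (offset 0.10, scale 0.45),
    ΔH = 22.0 kJ/mol and ΔS = 62.5 J/(mol·K); UBA-like binding with
    Kd = 4.9 µM at 50 µM protein and the canonical hydrophobic-patch
    attenuating set {L8, I44, A46, K48, Q49, H68}; SOFAST-HMQC-like
    noise (σ_H 0.003 ppm, σ_N 0.02 ppm, 5% intensity CV).
    """

    residues: list[int] = field(default_factory=_default_residues)
    # conformer population models
    pka_alt: float = 7.08
    pop_offset: float = 0.10
    pop_scale: float = 0.45
    delta_H: float = 22.0e3   # J/mol
    delta_S: float = 62.5     # J/(mol*K)
    # per-residue pH titration (fast exchange)
    pka_range: tuple[float, float] = (6.8, 7.4)
    dd_limit_range: tuple[float, float] = (0.05, 0.7)  # ppm, limiting CSP
    alt_damping: float = 0.3  # alt peaks move this fraction of the nat shift
    # binding model
    kd: float = 4.9e-6        # molar
    protein_total: float = 50e-6
    dmax_range: tuple[float, float] = (0.05, 0.40)  # ppm
    attenuating: frozenset[int] = frozenset({8, 44, 46, 48, 49, 68})
    attenuation_depth: float = 0.85  # endpoint intensity 1-depth*fb of start
    # relaxation model (600 MHz, 23 C monomeric Ub-like)
    r1_base: float = 1.4   # 1/s
    r2_base: float = 11.5  # 1/s
    exchange_elevations: dict[int, float] = field(
        default_factory=lambda: {3: 6.0, 63: 6.0, 73: 6.0}
    )
    # noise
    sigma_H: float = 0.003       # ppm
    sigma_N: float = 0.02        # ppm
    intensity_cv: float = 0.05   # multiplicative
    relax_cv: float = 0.05
    total_intensity: float = 1.0e6
    # planted defects for residue-selection tests
    overlap_pairs: list[tuple[int, int]] = field(default_factory=list)
    lost_residues: frozenset[int] = frozenset()
    no_alt_residues: frozenset[int] = frozenset()
    # reproducible layout (independent of the noise seed)
    layout_seed: int = 20180208
    seed: int = 0

    def __post_init__(self) -> None:
        self._layout_cache: dict | None = None

    # -- deterministic per-residue layout -----------------------------------
    def layout(self) -> dict:
        """Noise-free per-residue parameters, fixed by ``layout_seed``."""
        if self._layout_cache is not None:
            return self._layout_cache
        rng = np.random.default_rng(self.layout_seed)
        # default layouts are well resolved: every peak keeps clear of every
        # other at every default-grid pH point (overlaps are planted, never
        # accidental), so residue-selection tests have exact ground truth
        margin_H, margin_N = 0.07, 0.35
        grid = np.asarray(DEFAULT_PH_GRID)
        taken: list[np.ndarray] = []  # per accepted signal: (n_grid, 2) tracks

        def separated(track: np.ndarray) -> bool:
            return all(
                np.all(
                    np.hypot((track[:, 0] - other[:, 0]) / margin_H,
                             (track[:, 1] - other[:, 1]) / margin_N) > 1.0
                )
                for other in taken
            )

        layout: dict[int, dict] = {}
        for r in self.residues:
            for _ in range(1000):
                base_H = rng.uniform(6.8, 10.2)
                base_N = rng.uniform(105.0, 130.0)
                # alt-conformer peaks sit at a distinct offset from their nat partner
                alt_H = base_H + rng.uniform(0.1, 0.5) * rng.choice([-1, 1])
                alt_N = base_N + rng.uniform(0.5, 2.5) * rng.choice([-1, 1])
                phi = rng.uniform(0, 2 * math.pi)  # direction on the (H, N/5) unit circle
                pka = rng.uniform(*self.pka_range)
                dd_limit = rng.uniform(*self.dd_limit_range)
                uH, uN = math.cos(phi), math.sin(phi)
                x = np.power(10.0, grid - pka)
                theta = x / (1.0 + x)
                nat_track = np.column_stack([
                    base_H + theta * dd_limit * uH,
                    base_N + theta * dd_limit * uN * 5.0,
                ])
                alt_track = np.column_stack([
                    alt_H + self.alt_damping * theta * dd_limit * uH,
                    alt_N + self.alt_damping * theta * dd_limit * uN * 5.0,
                ])
                if separated(nat_track) and separated(alt_track) and np.all(
                    np.hypot((nat_track[:, 0] - alt_track[:, 0]) / margin_H,
                             (nat_track[:, 1] - alt_track[:, 1]) / margin_N) > 1.0
                ):
                    break
            else:  # pragma: no cover - layout space is nowhere near full
                raise RuntimeError(f"cannot place residue {r} without overlap")
            taken.extend([nat_track, alt_track])
            r1 = self.r1_base * rng.normal(1.0, 0.04)
            r2 = self.r2_base * rng.normal(1.0, 0.04)
            # flexible C-terminal tail: faster motions, lower R2 / higher R1
            if r >= 75:
                r2 *= 0.45
                r1 *= 1.1
            layout[r] = {
                "base_H": base_H, "base_N": base_N,
                "alt_H": alt_H, "alt_N": alt_N,
                "dir": (uH, uN),
                "pka": pka, "dd_limit": dd_limit,
                "dmax": rng.uniform(*self.dmax_range),
                "r1": r1, "r2": r2,
            }
        self._layout_cache = layout
        return self._layout_cache

    def residue_name(self, index: int) -> str:
        if 1 <= index <= len(UBIQUITIN_SEQUENCE):
            return UBIQUITIN_SEQUENCE[index - 1]
        return "X"

    def f_alt(self, pH: float) -> float:
        """Acid–base conformer population: offset + scale·θ(pH)."""
        x = 10.0 ** (pH - self.pka_alt)
        return self.pop_offset + self.pop_scale * x / (1.0 + x)

    def ratio_at_temperature(self, T: float) -> float:
        """Boltzmann intensity ratio I_alt/I_nat = exp(−ΔH/RT + ΔS/R)."""
        return math.exp(-self.delta_H / (R_GAS * T) + self.delta_S / R_GAS)

    def theta(self, pH: float, residue: int) -> float:
        pka = self.layout()[residue]["pka"]
        x = 10.0 ** (pH - pka)
        return x / (1.0 + x)

    # -- YAML round-trip -----------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d.pop("_layout_cache", None)
        d["attenuating"] = sorted(self.attenuating)
        d["lost_residues"] = sorted(self.lost_residues)
        d["no_alt_residues"] = sorted(self.no_alt_residues)
        d["overlap_pairs"] = [list(p) for p in self.overlap_pairs]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in ("attenuating", "lost_residues", "no_alt_residues"):
            if k in d:
                d[k] = frozenset(d[k])
        if "overlap_pairs" in d:
            d["overlap_pairs"] = [tuple(p) for p in d["overlap_pairs"]]
        for k in ("pka_range", "dd_limit_range", "dmax_range"):
            if k in d:
                d[k] = tuple(d[k])
        if "exchange_elevations" in d:
            d["exchange_elevations"] = {int(k): float(v) for k, v in d["exchange_elevations"].items()}
        return cls(**d)


def _noise_rng(truth: GroundTruth, stream: int) -> np.random.Generator:
    return np.random.default_rng([truth.seed, stream])


def _noisy_peak(rng, truth: GroundTruth, noise: bool, **kw) -> Peak:
    if noise:
        kw["shift_H"] += rng.normal(0.0, truth.sigma_H)
        kw["shift_N"] += rng.normal(0.0, truth.sigma_N)
        kw["intensity"] = max(kw["intensity"] * (1.0 + rng.normal(0.0, truth.intensity_cv)), 0.0)
    return Peak(**kw)


DEFAULT_PH_GRID = (4.6, 5.1, 5.6, 6.1, 6.6, 7.1, 7.6)
DEFAULT_T_GRID = (291.0, 294.0, 297.0, 300.0, 303.0, 306.0)


def gen_ph_series(
    truth: GroundTruth,
    ph_grid: tuple[float, ...] = DEFAULT_PH_GRID,
    noise: bool = True,
) -> TitrationSeries:
    """pH titration: fast-exchange shifts plus slow-exchange intensity split.

    Native peaks move along their fixed direction by θ(pH)·Δδ_limit in
    the combined-shift metric; alternate peaks move ``alt_damping`` of
    that.  Intensities split by the acid–base population model.  Planted
    defects (overlaps at the middle point, lost signals, missing alt
    peaks) support residue-selection tests.
    """
    layout = truth.layout()
    rng = _noise_rng(truth, 1)
    mid = len(ph_grid) // 2
    points = []
    for i, pH in enumerate(ph_grid):
        f = truth.f_alt(pH)
        peaks: list[Peak] = []
        pos: dict[int, tuple[float, float]] = {}
        for r in truth.residues:
            lay = layout[r]
            th = truth.theta(pH, r)
            uH, uN = lay["dir"]
            dH = th * lay["dd_limit"] * uH
            dN = th * lay["dd_limit"] * uN * 5.0
            pos[r] = (lay["base_H"] + dH, lay["base_N"] + dN)
        # planted overlaps: co-locate the pair at the middle titration point
        if i == mid:
            for a, b in truth.overlap_pairs:
                pos[b] = (pos[a][0] + 0.005, pos[a][1] + 0.02)
        for r in truth.residues:
            lay = layout[r]
            if r in truth.lost_residues and i == mid:
                continue
            h, n = pos[r]
            peaks.append(_noisy_peak(
                rng, truth, noise,
                residue_index=r, residue_name=truth.residue_name(r),
                site=Site.BACKBONE, conformer=Conformer.NAT,
                shift_H=h, shift_N=n,
                intensity=truth.total_intensity * (1.0 - f),
            ))
            if r in truth.no_alt_residues:
                continue
            th = truth.theta(pH, r)
            uH, uN = lay["dir"]
            d = truth.alt_damping * th * lay["dd_limit"]
            peaks.append(_noisy_peak(
                rng, truth, noise,
                residue_index=r, residue_name=truth.residue_name(r),
                site=Site.BACKBONE, conformer=Conformer.ALT,
                shift_H=lay["alt_H"] + d * uH, shift_N=lay["alt_N"] + d * uN * 5.0,
                intensity=truth.total_intensity * f,
            ))
        cond = Condition(pH=pH, temperature=296.15, buffer="citrate-phosphate")
        points.append(PeakList(peaks, cond, label=f"pH{pH:g}"))
    return TitrationSeries(points, varying="pH", reference_index=len(ph_grid) - 1)


def gen_temperature_series(
    truth: GroundTruth,
    t_grid: tuple[float, ...] = DEFAULT_T_GRID,
    noise: bool = True,
    pH: float = 6.8,
) -> TitrationSeries:
    """Temperature series: Boltzmann intensity ratios, static shifts."""
    layout = truth.layout()
    rng = _noise_rng(truth, 2)
    points = []
    for T in t_grid:
        ratio = truth.ratio_at_temperature(T)
        f = ratio / (1.0 + ratio)
        peaks: list[Peak] = []
        for r in truth.residues:
            lay = layout[r]
            peaks.append(_noisy_peak(
                rng, truth, noise,
                residue_index=r, residue_name=truth.residue_name(r),
                site=Site.BACKBONE, conformer=Conformer.NAT,
                shift_H=lay["base_H"], shift_N=lay["base_N"],
                intensity=truth.total_intensity * (1.0 - f),
            ))
            if r in truth.no_alt_residues:
                continue
            peaks.append(_noisy_peak(
                rng, truth, noise,
                residue_index=r, residue_name=truth.residue_name(r),
                site=Site.BACKBONE, conformer=Conformer.ALT,
                shift_H=lay["alt_H"], shift_N=lay["alt_N"],
                intensity=truth.total_intensity * f,
            ))
        cond = Condition(pH=pH, temperature=T, buffer="sodium phosphate")
        points.append(PeakList(peaks, cond, label=f"{T:g}K"))
    return TitrationSeries(points, varying="temperature")


def gen_binding_series(
    truth: GroundTruth,
    equivalents: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0),
    dilution: bool = True,
    stock_ratio: float = 20.0,
    noise: bool = True,
    pH: float = 6.8,
) -> TitrationSeries:
    """Ligand titration following the exact single-site isotherm.

    ``equivalents`` is the target [L]t/[P]t schedule.  With ``dilution``
    the ligand is added from a stock ``stock_ratio``× the starting
    protein concentration and both totals are diluted accordingly (as in
    a real titration); the per-point totals are stored in each
    condition.  Non-attenuating residues trace straight-line trajectories
    scaled by the isotherm; planted interface residues instead lose
    intensity linearly in the bound fraction, to below 25% of the start
    at saturation.  Alternate-conformer intensities are depleted in
    proportion to the bound fraction (ligand binds the native conformer
    only).
    """
    layout = truth.layout()
    rng = _noise_rng(truth, 3)
    P0 = truth.protein_total
    f_alt0 = truth.f_alt(pH)
    points = []
    for eq in equivalents:
        if dilution and eq > 0:
            # v solves L_t/P_t = eq with L_t = stock*v/(V0+v), P_t = P0*V0/(V0+v)
            v = eq * P0 / (stock_ratio * P0)  # volume fraction of V0
            P_t = P0 / (1.0 + v)
            L_t = stock_ratio * P0 * v / (1.0 + v)
        else:
            P_t, L_t = P0, eq * P0
        fb = float(bound_fraction(P_t, L_t, truth.kd))
        peaks: list[Peak] = []
        for r in truth.residues:
            lay = layout[r]
            uH, uN = lay["dir"]
            dd = lay["dmax"] * fb
            if r in truth.attenuating:
                nat_intensity = truth.total_intensity * (1.0 - f_alt0) * max(
                    1.0 - truth.attenuation_depth * fb, 0.0
                )
            else:
                nat_intensity = truth.total_intensity * (1.0 - f_alt0)
            peaks.append(_noisy_peak(
                rng, truth, noise,
                residue_index=r, residue_name=truth.residue_name(r),
                site=Site.BACKBONE, conformer=Conformer.NAT,
                shift_H=lay["base_H"] + dd * uH, shift_N=lay["base_N"] + dd * uN * 5.0,
                intensity=nat_intensity,
            ))
            if r in truth.no_alt_residues:
                continue
            peaks.append(_noisy_peak(
                rng, truth, noise,
                residue_index=r, residue_name=truth.residue_name(r),
                site=Site.BACKBONE, conformer=Conformer.ALT,
                shift_H=lay["alt_H"], shift_N=lay["alt_N"],
                intensity=truth.total_intensity * f_alt0 * (1.0 - fb),
            ))
        cond = Condition(pH=pH, temperature=296.15, ligand_total=L_t, protein_total=P_t,
                         buffer="sodium phosphate")
        points.append(PeakList(peaks, cond, label=f"{eq:g}eq"))
    return TitrationSeries(points, varying="ligand")


def gen_relaxation(
    truth: GroundTruth,
    mode: str = "monomer",
    noise: bool = True,
) -> list[RelaxationRecord]:
    """15N rate tables for the nat and alt signal groups.

    ``mode="monomer"`` gives both groups the same rotational-diffusion
    baseline (a genuine conformer); ``mode="dimer"`` scales the alt
    group's R2 by 1.6 and R1 by 1/1.6 (an oligomerization artifact).
    Planted μs–ms exchange elevations are added to the alt group's R2.
    """
    if mode not in ("monomer", "dimer"):
        raise ValueError(f"mode must be 'monomer' or 'dimer', got {mode!r}")
    layout = truth.layout()
    rng = _noise_rng(truth, 4)
    records: list[RelaxationRecord] = []
    for r in truth.residues:
        lay = layout[r]
        for conformer in (Conformer.NAT, Conformer.ALT):
            r1, r2 = lay["r1"], lay["r2"]
            if conformer is Conformer.ALT:
                if mode == "dimer":
                    r1 /= DIMER_FACTOR
                    r2 *= DIMER_FACTOR
                r2 += truth.exchange_elevations.get(r, 0.0)
            if noise:
                r1 = max(r1 * (1.0 + rng.normal(0.0, truth.relax_cv)), 1e-6)
                r2 = max(r2 * (1.0 + rng.normal(0.0, truth.relax_cv)), 1e-6)
            records.append(RelaxationRecord(
                r, conformer, R1=r1, R2=r2,
                R1_err=truth.relax_cv * r1, R2_err=truth.relax_cv * r2,
            ))
    return records
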