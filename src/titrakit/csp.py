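"""Chemical-shift-perturbation (CSP) analysis.

The combined amide CSP between two states is

    Δδ = sqrt(Δδ_H² + (Δδ_N / 5)²)

with the conventional 1/5 weighting of the ¹⁵N dimension (exposed as
``scale_N``).  CSP profiles along the sequence locate perturbed surfaces
(binding interfaces, mutation sites); normalized pH-titration CSPs feed
the pKa fits of :mod:`titrakit.equilibrium`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .peakdata import Conformer, PeakList, Site, Trajectory

__all__ = ["CSPRecord", "compute_csp", "normalized_csp", "csp_profile"]


@dataclass(frozen=True)
class CSPRecord:
    """Per-residue shift perturbation between a reference and a state."""

    residue_index: int
    conformer: Conformer
    delta_H: float  # ppm, signed (state - reference)
    delta_N: float  # ppm, signed
    csp: float      # ppm, combined
    site: Site = Site.BACKBONE
    reference_label: str = ""
    state_label: str = ""


def combined_csp(delta_H: float, delta_N: float, scale_N: float = 5.0) -> float:
    """Δδ = sqrt(Δδ_H² + (Δδ_N/scale_N)²)."""
    if scale_N <= 0:
        raise ValueError(f"scale_N must be > 0, got {scale_N}")
    return math.hypot(delta_H, delta_N / scale_N)


def compute_csp(
    reference: PeakList,
    state: PeakList,
    scale_N: float = 5.0,
) -> tuple[list[CSPRecord], list[tuple[int, Site, Conformer]]]:
    """CSPs for every (residue, site, conformer) shared by both lists.

    Returns (records, missing) where ``missing`` lists the keys present
    in exactly one of the two lists — reported, not silently dropped.
    """
    if scale_N <= 0:
        raise ValueError(f"scale_N must be > 0, got {scale_N}")
    ref_peaks = {p.key: p for p in reference}
    state_peaks = {p.key: p for p in state}
    shared = sorted(ref_peaks.keys() & state_peaks.keys())
    missing = sorted(ref_peaks.keys() ^ state_peaks.keys())
    records = []
    for key in shared:
        a, b = ref_peaks[key], state_peaks[key]
        dH = b.shift_H - a.shift_H
        dN = b.shift_N - a.shift_N
        records.append(
            CSPRecord(
                residue_index=key[0],
                conformer=key[2],
                delta_H=dH,
                delta_N=dN,
                csp=combined_csp(dH, dN, scale_N),
                site=key[1],
                reference_label=reference.label,
                state_label=state.label,
            )
        )
    return records, missing


def normalized_csp(
    trajectory: Trajectory,
    baseline_pH: float = 4.8,
    reference_pH: float = 7.6,
    scale_N: float = 5.0,
) -> pd.Series:
    """Normalized pH-titration CSP for one residue trajectory.

    At each pH the CSP is measured against the signal position at
    ``baseline_pH``; values are then divided by the CSP at
    ``reference_pH`` so that the curve is exactly 1 at the reference and
    0 at the baseline.  Raises when the reference CSP is zero (the
    normalization is undefined for a stationary signal).
    """
    base = trajectory.point_at(baseline_pH)
    ref = trajectory.point_at(reference_pH)
    ref_csp = combined_csp(ref.shift_H - base.shift_H, ref.shift_N - base.shift_N, scale_N)
    if ref_csp == 0.0:
        raise ZeroDivisionError(
            f"residue {trajectory.residue_index}: CSP at the reference pH is zero; "
            "normalization undefined"
        )
    values = {
        p.condition_value: combined_csp(
            p.shift_H - base.shift_H, p.shift_N - base.shift_N, scale_N
        ) / ref_csp
        for p in trajectory.points
    }
    s = pd.Series(values, name=f"res{trajectory.residue_index}").sort_index()
    s.index.name = "pH"
    return s


def csp_profile(records: list[CSPRecord], threshold: float = 0.1) -> pd.DataFrame:
    """Per-residue CSP table ordered by residue index.

    Sequence gaps (prolines, unassigned residues) appear as NaN rows so
    the profile is explicit about what was not observed.  The frame's
    ``attrs`` carry the summary: mean and max CSP and the residues above
    ``threshold``.
    """
    if not records:
        df = pd.DataFrame(columns=["delta_H", "delta_N", "csp"])
        df.index.name = "residue_index"
        df.attrs.update({"mean": float("nan"), "max": float("nan"), "above_threshold": []})
        return df
    rows = {
        r.residue_index: {"delta_H": r.delta_H, "delta_N": r.delta_N, "csp": r.csp}
        for r in records
        if r.site is Site.BACKBONE
    }
    full_index = range(min(rows), max(rows) + 1)
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(full_index)
    df.index.name = "residue_index"
    above = df.index[df["csp"] > threshold].tolist()
    df.attrs.update(
        {"mean": float(df["csp"].mean()), "max": float(df["csp"].max()),
         "above_threshold": above}
    )
    return df
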