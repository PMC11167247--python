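"""Sequence- and structure-based developability descriptors.

Charge descriptors follow the Henderson–Hasselbalch convention with the
EMBOSS pKa set: a basic site contributes 1/(1+10^(pH−pKa)), an acidic site
−1/(1+10^(pKa−pH)). The two charge-symmetry descriptors of the Fv are

    FvCSP   = q_VL · q_VH        (charge symmetry parameter, e²)
    Fv_chml = q_VH − q_VL        (heavy/light charge imbalance, e)

and the normalised hydrophobic score is the fraction of the solvent-
accessible surface covered by hydrophobic patches, Σ res_hyd / Σ res_ASA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .surface import PatchSummary, ResidueContribution
from .tables import ACIDIC, BASIC, EMBOSS_PKA


@dataclass(frozen=True)
class ChargeModel:
    """pKa table for titratable side chains (D,E,C,Y,H,K,R) and termini."""

    pka_table: dict[str, float] = field(default_factory=lambda: dict(EMBOSS_PKA))
    include_termini: bool = True

    def __post_init__(self) -> None:
        for name, pka in self.pka_table.items():
            if not 0.0 < pka < 14.0:
                raise ValueError(f"pKa for {name} out of range: {pka}")


def net_charge(sequence: str, pH: float, charge_model: ChargeModel | None = None) -> float:
    """Net charge (e) of a free polypeptide at the given pH."""
    cm = charge_model or ChargeModel()
    if not sequence:
        raise ValueError("sequence is empty")
    pka = cm.pka_table
    q = 0.0
    for aa in sequence:
        if aa == "X":
            continue
        if aa not in "ACDEFGHIKLMNPQRSTVWY":
            raise ValueError(f"unknown amino acid letter {aa!r}")
        if aa in BASIC:
            q += 1.0 / (1.0 + 10.0 ** (pH - pka[aa]))
        elif aa in ACIDIC:
            q -= 1.0 / (1.0 + 10.0 ** (pka[aa] - pH))
    if cm.include_termini:
        q += 1.0 / (1.0 + 10.0 ** (pH - pka["N_term"]))
        q -= 1.0 / (1.0 + 10.0 ** (pka["C_term"] - pH))
    return q


class NoIsoelectricPointError(ValueError):
    """The sequence's charge never crosses zero on pH 0–14."""


def isoelectric_point(sequence: str, charge_model: ChargeModel | None = None) -> float:
    """pH at which the net charge is zero (Brent root on [0, 14]).

    Net charge is monotone non-increasing in pH, so the root is unique when
    the sequence carries at least one acidic and one basic site.
    """
    cm = charge_model or ChargeModel()
    lo, hi = net_charge(sequence, 0.0, cm), net_charge(sequence, 14.0, cm)
    if lo <= 0.0 or hi >= 0.0:
        raise NoIsoelectricPointError(
            "net charge does not change sign on pH 0-14; no isoelectric point"
        )
    return float(brentq(lambda p: net_charge(sequence, p, cm), 0.0, 14.0, xtol=1e-6))


def fv_csp(q_vl: float, q_vh: float) -> float:
    """Fv charge symmetry parameter: the product of the VL and VH net charges."""
    return q_vl * q_vh


def fv_chml(q_vl: float, q_vh: float) -> float:
    """Heavy/light chain charge imbalance: VH net charge minus VL net charge."""
    return q_vh - q_vl


def normalised_hydrophobic_score(contributions: list[ResidueContribution]) -> float:
    """Fraction of exposed surface in hydrophobic patches: Σres_hyd / Σres_ASA."""
    total_asa = sum(c.res_asa for c in contributions)
    if total_asa <= 0:
        raise ValueError("total accessible surface area is zero")
    return sum(c.res_hyd for c in contributions) / total_asa


#: canonical descriptor-table column order
DESCRIPTOR_COLUMNS = [
    "q_VL", "q_VH", "net_charge_fv", "FvCSP", "Fv_chml", "pI_seq",
    "norm_hyd_score", "hyd_area_A2", "pos_area_A2", "neg_area_A2",
    "n_hyd_patches", "n_patches_near_cdr",
]


@dataclass
class VariantRecord:
    """One panel member: sequences plus optional patch-analysis outputs."""

    variant_id: str
    vl_sequence: str
    vh_sequence: str
    contributions: list[ResidueContribution] | None = None
    summary: PatchSummary | None = None


def build_descriptor_table(
    variants: list[VariantRecord],
    pH: float = 6.0,
    charge_model: ChargeModel | None = None,
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the per-variant descriptor table.

    Charge columns are always emitted; patch columns appear only for
    variants that carry patch outputs. ``extra`` (indexed or keyed by
    variant_id) merges external descriptor columns such as aggregation-
    propensity or literature viscosity-model scores.
    """
    cm = charge_model or ChargeModel()
    ids = [v.variant_id for v in variants]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate variant_id in panel")

    rows = []
    for v in variants:
        q_vl = net_charge(v.vl_sequence, pH, cm)
        q_vh = net_charge(v.vh_sequence, pH, cm)
        row: dict[str, float | str | None] = {
            "variant_id": v.variant_id,
            "q_VL": q_vl,
            "q_VH": q_vh,
            "net_charge_fv": q_vl + q_vh,
            "FvCSP": fv_csp(q_vl, q_vh),
            "Fv_chml": fv_chml(q_vl, q_vh),
        }
        try:
            row["pI_seq"] = isoelectric_point(v.vl_sequence + v.vh_sequence, cm)
        except NoIsoelectricPointError:
            row["pI_seq"] = np.nan
        if v.contributions is not None:
            row["norm_hyd_score"] = normalised_hydrophobic_score(v.contributions)
        if v.summary is not None:
            row["hyd_area_A2"] = v.summary.total_area["hydrophobic"]
            row["pos_area_A2"] = v.summary.total_area["positive"]
            row["neg_area_A2"] = v.summary.total_area["negative"]
            row["n_hyd_patches"] = v.summary.patch_count["hydrophobic"]
            row["n_patches_near_cdr"] = sum(v.summary.near_cdr_count.values())
        rows.append(row)

    table = pd.DataFrame(rows).set_index("variant_id")
    if extra is not None:
        ex = extra.copy()
        if "variant_id" in ex.columns:
            ex = ex.set_index("variant_id")
        table = table.join(ex, how="left")
    ordered = [c for c in DESCRIPTOR_COLUMNS if c in table.columns]
    rest = [c for c in table.columns if c not in ordered]
    return table[ordered + rest]
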