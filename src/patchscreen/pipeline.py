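"""End-to-end orchestration: the structure screen and the measurement fits.

``run_screen`` chains patch analysis → residue contributions → descriptors
→ mutation design → triage ranking and writes per-stage CSVs plus a run
manifest (config hash, package version, seed, per-file checksums).
``run_fits`` applies the measurement models per variant and emits fit and
correlation reports. Both are deterministic given (config, seed, inputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biophys import (
    ConcentrationSeries,
    SpectrumTrace,
    Thermogram,
    acsins_redshift,
    correlation_matrix,
    dsf_transitions,
    fit_kd,
    fit_viscosity,
)
from .descriptors import net_charge, fv_csp, fv_chml, normalised_hydrophobic_score
from .design import (
    DEFAULT_STRATEGIES,
    MutationCandidate,
    enumerate_mutations,
    mutate_structure_naive,
    rank_patch_residues,
)
from .structure import (
    StructureModel,
    annotate_regions,
    extract_sequence,
    read_region_map,
    read_structure,
)
from .surface import (
    PatchParams,
    assign_surface_values,
    compute_sasa,
    detect_patches,
    patch_summary,
    residue_patch_contributions,
)
from .triage import rank_panel

logger = logging.getLogger(__name__)

#: directions for the descriptors the screen itself computes; hydrophobicity
#: descriptors correlate positively with elevated viscosity
SCREEN_DIRECTIONS = {"norm_hyd_score": "positive", "hyd_area_A2": "positive"}


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class RunConfig:
    structure: str | None = None
    region_map: str | None = None
    chain_roles: dict[str, str] = field(default_factory=dict)
    pH: float = 6.0
    top_n: int = 5
    patch_params: PatchParams = field(default_factory=PatchParams)
    dielectric: float | str = "4r"
    directions: dict[str, str] = field(default_factory=lambda: dict(SCREEN_DIRECTIONS))
    weights: dict[str, float] | None = None
    out_dir: str = "patchscreen_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "patch_params" in raw:
            raw["patch_params"] = PatchParams(**raw["patch_params"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out_dir: Path, config: RunConfig, files: list[Path]) -> Path:
    config_blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "config": json.loads(config_blob),
        "outputs": {f.name: _sha256(f) for f in sorted(files)},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def analyze_structure(
    model: StructureModel, params: PatchParams, dielectric: float | str = "4r"
):
    """Patch analysis of one model: SASA, valued cloud, patches, res
    contributions, per-class summary."""
    sasa = compute_sasa(model, params)
    cloud = assign_surface_values(sasa.cloud, model, dielectric=dielectric)
    patches = detect_patches(cloud, params, model)
    contribs = residue_patch_contributions(patches, sasa)
    summary = patch_summary(patches, model)
    return sasa, cloud, patches, contribs, summary


def _patches_frame(patches, model) -> pd.DataFrame:
    rows = []
    for i, p in enumerate(patches):
        residues = sorted(p.residue_shares)
        rows.append(
            {
                "patch_id": i,
                "class": p.patch_class,
                "area_A2": round(p.area, 4),
                "n_residues": len(residues),
                "near_cdr": p.near_cdr,
                "residues": ";".join(
                    f"{model.residues[r].chain_id}{model.residues[r].position_label}"
                    for r in residues
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["patch_id", "class", "area_A2", "n_residues", "near_cdr", "residues"]
    )


def _contributions_frame(contribs, model) -> pd.DataFrame:
    rows = []
    for c in contribs:
        res = model.residues[c.residue_index]
        rows.append(
            {
                "chain_id": res.chain_id,
                "position": res.position_label,
                "amino_acid": res.amino_acid,
                "region": res.region,
                "res_ASA": round(c.res_asa, 4),
                "res_hyd": round(c.res_hyd, 4),
                "res_pos": round(c.res_pos, 4),
                "res_neg": round(c.res_neg, 4),
            }
        )
    return pd.DataFrame(rows)


def _variant_descriptor_row(model: StructureModel, contribs, summary, pH: float) -> dict:
    row = {
        "norm_hyd_score": normalised_hydrophobic_score(contribs),
        "hyd_area_A2": summary.total_area["hydrophobic"],
        "pos_area_A2": summary.total_area["positive"],
        "neg_area_A2": summary.total_area["negative"],
        "n_hyd_patches": summary.patch_count["hydrophobic"],
        "n_patches_near_cdr": sum(summary.near_cdr_count.values()),
    }
    roles = set(model.chain_roles.values())
    if {"VH", "VL"} <= roles:
        q_vl = net_charge(extract_sequence(model, model.chain_for_role("VL")), pH)
        q_vh = net_charge(extract_sequence(model, model.chain_for_role("VH")), pH)
        row.update(
            q_VL=q_vl,
            q_VH=q_vh,
            net_charge_fv=q_vl + q_vh,
            FvCSP=fv_csp(q_vl, q_vh),
            Fv_chml=fv_chml(q_vl, q_vh),
        )
    return row


def run_screen(
    config: RunConfig, model: StructureModel | None = None
) -> dict[str, pd.DataFrame]:
    """Execute the full structure screen and write the report bundle.

    Returns the per-stage tables; files land in ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = config.patch_params

    # -- stage: structure ---------------------------------------------------
    if model is None:
        if config.structure is None:
            raise StageError("structure: no structure path or model supplied")
        try:
            model = read_structure(config.structure)
        except Exception as exc:
            raise StageError(f"structure: {exc}") from exc
    try:
        region_rows = read_region_map(config.region_map) if config.region_map else []
        model = annotate_regions(model, region_rows, config.chain_roles or model.chain_roles)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"annotate_regions: {exc}") from exc

    # -- stage: patches -----------------------------------------------------
    try:
        sasa, cloud, patches, contribs, summary = analyze_structure(
            model, params, config.dielectric
        )
    except Exception as exc:
        raise StageError(f"patches: {exc}") from exc

    # -- stage: design ------------------------------------------------------
    try:
        candidates: list[MutationCandidate] = []
        for strategy in DEFAULT_STRATEGIES:
            ranked = rank_patch_residues(
                contribs, model, strategy.patch_class, top_n=config.top_n
            )
            candidates.extend(enumerate_mutations(ranked, model, strategy))
    except Exception as exc:
        raise StageError(f"design: {exc}") from exc

    # -- stage: descriptors (WT + each candidate via naive structural mutation)
    try:
        rows = {"WT": _variant_descriptor_row(model, contribs, summary, config.pH)}
        for cand in candidates:
            mutant = mutate_structure_naive(model, cand)
            _, _, m_patches, m_contribs, m_summary = analyze_structure(
                mutant, params, config.dielectric
            )
            rows[cand.variant_id] = _variant_descriptor_row(
                mutant, m_contribs, m_summary, config.pH
            )
        table = pd.DataFrame.from_dict(rows, orient="index")
        table.index.name = "variant_id"
    except Exception as exc:
        raise StageError(f"descriptors: {exc}") from exc

    # -- stage: rank --------------------------------------------------------
    try:
        ranked_panel = rank_panel(
            table, directions=config.directions, weights=config.weights
        )
    except Exception as exc:
        raise StageError(f"rank: {exc}") from exc

    cand_frame = pd.DataFrame(
        [
            {
                "variant_id": c.variant_id,
                "chain": c.chain_id,
                "position": c.position_label,
                "wt": c.wt_residue,
                "new": c.new_residue,
                "strategy": c.strategy_name,
                "patch_class": c.targeted_patch_class,
                "contribution_A2": round(c.source_contribution, 4),
            }
            for c in candidates
        ],
        columns=["variant_id", "chain", "position", "wt", "new", "strategy",
                 "patch_class", "contribution_A2"],
    )

    outputs = {
        "patches": _patches_frame(patches, model),
        "contributions": _contributions_frame(contribs, model),
        "candidates": cand_frame,
        "descriptors": table.reset_index(),
        "ranked_panel": ranked_panel.reset_index(names="variant_id"),
    }
    files = []
    for name, frame in outputs.items():
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False, float_format="%.6g")
        files.append(path)

    # mutated sequence per candidate, one FASTA record each
    from .design import apply_mutation
    from .structure import write_fasta

    records: dict[str, str] = {}
    for cand in candidates:
        chain_positions = [
            r.position_label for r in model.residues if r.chain_id == cand.chain_id
        ]
        seq = extract_sequence(model, cand.chain_id)
        pos = chain_positions.index(cand.position_label) + 1
        records[f"{cand.chain_id}_{cand.variant_id}"] = apply_mutation(seq, cand, pos)
    if records:
        fasta_path = out_dir / "mutants.fasta"
        write_fasta(records, fasta_path)
        files.append(fasta_path)

    _write_manifest(out_dir, config, files)
    return outputs


# ---------------------------------------------------------------------------
# measurement fits
# ---------------------------------------------------------------------------

def fit_kd_table(data: pd.DataFrame) -> pd.DataFrame:
    """Per-variant kD fits from long-format (variant_id, conc_mg_ml, Dapp)."""
    rows = []
    for vid, grp in data.groupby("variant_id", sort=True):
        row = {"variant_id": vid}
        try:
            fit = fit_kd(
                ConcentrationSeries(
                    grp["conc_mg_ml"].to_numpy(), grp["Dapp"].to_numpy()
                )
            )
            row.update(
                D0=fit.d0, kD_ml_per_mg=fit.kd, kD_ml_per_g=fit.kd_ml_per_g,
                kD_se=fit.kd_se, R2=fit.r_squared,
                flag_attractive=fit.flag_attractive, error="",
            )
        except Exception as exc:
            row["error"] = str(exc)
            logger.warning("kD fit failed for %s: %s", vid, exc)
        rows.append(row)
    return pd.DataFrame(rows)


def fit_viscosity_table(data: pd.DataFrame) -> pd.DataFrame:
    """Per-variant exponential fits from (variant_id, conc_mg_ml, eta_cP)."""
    rows = []
    for vid, grp in data.groupby("variant_id", sort=True):
        row = {"variant_id": vid}
        try:
            fit = fit_viscosity(
                ConcentrationSeries(
                    grp["conc_mg_ml"].to_numpy(), grp["eta_cP"].to_numpy()
                )
            )
            row.update(
                Y0_cP=fit.y0, k_ml_per_mg=fit.k, Y0_se=fit.y0_se, k_se=fit.k_se,
                c_at_30cP_mg_ml=fit.c_at_30cp if fit.c_at_30cp is not None else np.nan,
                error="",
            )
        except Exception as exc:
            row["error"] = str(exc)
            logger.warning("viscosity fit failed for %s: %s", vid, exc)
        rows.append(row)
    return pd.DataFrame(rows)


def acsins_table(spectra: pd.DataFrame, control_column: str = "control") -> pd.DataFrame:
    """Red shifts from a wide spectra table (wavelength_nm, control, <variants>)."""
    wl = spectra["wavelength_nm"].to_numpy(dtype=float)
    control = SpectrumTrace(wl, spectra[control_column].to_numpy(dtype=float))
    rows = []
    for col in spectra.columns:
        if col in ("wavelength_nm", control_column):
            continue
        row = {"variant_id": col}
        try:
            res = acsins_redshift(SpectrumTrace(wl, spectra[col].to_numpy(dtype=float)), control)
            row.update(
                redshift_nm=res.delta_lambda_nm,
                sample_peak_nm=res.sample_peak_nm,
                control_peak_nm=res.control_peak_nm,
                flag_self_association=res.flag_self_association,
                error="",
            )
        except Exception as exc:
            row["error"] = str(exc)
            logger.warning("AC-SINS analysis failed for %s: %s", col, exc)
        rows.append(row)
    return pd.DataFrame(rows)


def dsf_table(data: pd.DataFrame) -> pd.DataFrame:
    """Per-variant DSF calls from long (variant_id, temp_C, ratio[, scattering])."""
    rows = []
    for vid, grp in data.groupby("variant_id", sort=True):
        row = {"variant_id": vid}
        try:
            scat = (
                grp["scattering"].to_numpy(dtype=float)
                if "scattering" in grp.columns and grp["scattering"].notna().all()
                else None
            )
            res = dsf_transitions(
                Thermogram(
                    grp["temp_C"].to_numpy(dtype=float),
                    grp["ratio"].to_numpy(dtype=float),
                    scat,
                )
            )
            tms = list(res.tm) + [np.nan] * (3 - len(res.tm))
            row.update(
                Tonset_C=res.tonset if res.tonset is not None else np.nan,
                Tm1_C=tms[0], Tm2_C=tms[1], Tm3_C=tms[2],
                Tagg_C=res.tagg if res.tagg is not None else np.nan,
                error="",
            )
        except Exception as exc:
            row["error"] = str(exc)
            logger.warning("DSF analysis failed for %s: %s", vid, exc)
        rows.append(row)
    return pd.DataFrame(rows)


def run_fits(
    out_dir: str | Path,
    kd_data: pd.DataFrame | None = None,
    viscosity_data: pd.DataFrame | None = None,
    spectra: pd.DataFrame | None = None,
    thermograms: pd.DataFrame | None = None,
    descriptors: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Fit every supplied measurement table and correlate against descriptors.

    Per-variant failures are reported in the output tables' ``error`` column
    and do not stop the run. When a descriptor table is supplied, its
    columns are correlated (Pearson, strong |R| >= 0.8 flag) against the
    scalar fit results.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, pd.DataFrame] = {}
    if kd_data is not None:
        outputs["kd_fits"] = fit_kd_table(kd_data)
    if viscosity_data is not None:
        outputs["viscosity_fits"] = fit_viscosity_table(viscosity_data)
    if spectra is not None:
        outputs["acsins"] = acsins_table(spectra)
    if thermograms is not None:
        outputs["dsf"] = dsf_table(thermograms)

    if descriptors is not None and outputs:
        measure_cols = {}
        for name, frame, col in (
            ("kD_ml_per_g", outputs.get("kd_fits"), "kD_ml_per_g"),
            ("k_visc", outputs.get("viscosity_fits"), "k_ml_per_mg"),
            ("redshift_nm", outputs.get("acsins"), "redshift_nm"),
            ("Tm1_C", outputs.get("dsf"), "Tm1_C"),
        ):
            if frame is not None and col in frame.columns:
                measure_cols[name] = frame.set_index("variant_id")[col]
        if measure_cols:
            measurements = pd.DataFrame(measure_cols)
            desc = descriptors.set_index("variant_id") if "variant_id" in descriptors.columns else descriptors
            desc = desc.select_dtypes(include=[np.number])
            outputs["correlations"] = correlation_matrix(desc, measurements)

    for name, frame in outputs.items():
        frame.to_csv(out_dir / f"{name}.csv", index=False, float_format="%.6g")
    return outputs
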