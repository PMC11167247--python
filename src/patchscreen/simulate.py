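"""Synthetic data with known ground truth for every pipeline stage.

Generators are pure functions of (parameters, seed): toy one-bead-per-
residue structures with designed surface clusters, DLS series from the
interaction-parameter line, viscosity series from the exponential-growth
model, Gaussian plasmon spectra on the AC-SINS 450–650 nm grid, and
sigmoidal 350/330 unfolding thermograms over the 20–95 °C ramp. Each
dataset ships with a SimulationTruth record of its generating parameters.

Toy structures place one Cα-like pseudo-atom per residue on a spherical
Fibonacci lattice (or an ideal helix), so patch areas and memberships are
fixed by construction: full side-chain geometry is unnecessary to exercise
the thresholding and clustering machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .biophys import ConcentrationSeries, SpectrumTrace, Thermogram
from .structure import AtomRecord, ResidueRecord, StructureModel
from .surface import unit_sphere_points


@dataclass(frozen=True)
class ClusterSpec:
    patch_class: str      # hydrophobic | positive | negative
    n_residues: int
    # residue identity used for cluster members; background is Ser (polar,
    # negative on the shifted hydrophobicity scale, uncharged)
    residue: str | None = None


@dataclass(frozen=True)
class PatchSpec:
    clusters: tuple[ClusterSpec, ...] = ()
    n_residues: int = 60
    scaffold: str = "sphere_lattice"   # or "ideal_helix"
    # 9 Å with 3 Å beads keeps neighbouring beads overlapping enough that the
    # shell has no solvent-accessible inner surface (a single closed surface)
    sphere_radius: float = 9.0         # Å
    bead_radius: float = 3.0           # Å, pseudo-atom vdW radius
    seed: int = 0


@dataclass(frozen=True)
class SimulationTruth:
    params: dict[str, Any]
    seed: int


_CLUSTER_DEFAULT_RESIDUE = {"hydrophobic": "W", "positive": "K", "negative": "D"}


def make_toy_structure(spec: PatchSpec) -> tuple[StructureModel, list[set[int]]]:
    """Build a pseudo-residue structure with designed surface clusters.

    Returns the model and, per cluster, the set of residue indices that were
    assigned to it — the ground truth a patch detector should recover.
    Cluster members are chosen as contiguous runs of neighbouring lattice
    sites so each cluster is spatially compact and clusters never overlap.
    """
    n = spec.n_residues
    total_needed = sum(c.n_residues for c in spec.clusters)
    if total_needed > n:
        raise ValueError(
            f"clusters need {total_needed} residues but scaffold has {n}"
        )
    rng = np.random.default_rng(spec.seed)

    if spec.scaffold == "sphere_lattice":
        positions = spec.sphere_radius * unit_sphere_points(n)
    elif spec.scaffold == "ideal_helix":
        i = np.arange(n, dtype=float)
        positions = np.column_stack(
            (2.3 * np.cos(i * 100 * np.pi / 180),
             2.3 * np.sin(i * 100 * np.pi / 180),
             1.5 * i)
        )
    else:
        raise ValueError(f"unknown scaffold {spec.scaffold!r}")

    # grow each cluster from a well-separated seed site by nearest neighbours
    assigned = np.full(n, -1, dtype=int)
    d2 = ((positions[:, None, :] - positions[None, :, :]) ** 2).sum(axis=2)
    cluster_members: list[set[int]] = []
    seeds_taken: list[int] = []
    for ci, cluster in enumerate(spec.clusters):
        free = np.flatnonzero(assigned < 0)
        if seeds_taken:
            # pick the free site farthest from existing clusters
            dist_to_taken = d2[np.ix_(free, np.flatnonzero(assigned >= 0))].min(axis=1)
            seed_site = int(free[np.argmax(dist_to_taken)])
        else:
            seed_site = int(free[rng.integers(len(free))])
        order = np.argsort(d2[seed_site])
        members: set[int] = set()
        for j in order:
            if assigned[j] < 0:
                members.add(int(j))
                assigned[j] = ci
            if len(members) == cluster.n_residues:
                break
        cluster_members.append(members)
        seeds_taken.append(seed_site)

    atoms: list[AtomRecord] = []
    residues: list[ResidueRecord] = []
    for i in range(n):
        if assigned[i] >= 0:
            cluster = spec.clusters[assigned[i]]
            aa = cluster.residue or _CLUSTER_DEFAULT_RESIDUE[cluster.patch_class]
        else:
            aa = "S"
        residues.append(ResidueRecord("A", str(i + 1), aa))
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name="CA",
                element="C",
                residue_index=i,
                coordinates=tuple(float(x) for x in positions[i]),
                vdw_radius=spec.bead_radius,
            )
        )
    if spec.scaffold == "sphere_lattice":
        # buried neutral core filling the shell's interior, so the lattice has
        # a single closed outer surface and no spurious inner-cavity dots
        residues.append(ResidueRecord("A", str(n + 1), "G"))
        atoms.append(
            AtomRecord(
                serial=n + 1,
                name="CA",
                element="C",
                residue_index=n,
                coordinates=tuple(positions.mean(axis=0)),
                vdw_radius=max(1.0, spec.sphere_radius - spec.bead_radius - 1.0),
            )
        )
    model = StructureModel(atoms=atoms, residues=residues, chain_roles={"A": "other"})
    return model, cluster_members


def simulate_dls(
    d0: float,
    kd: float,
    conc_grid,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[ConcentrationSeries, SimulationTruth]:
    """Dapp = D0·(1 + kD·c) plus Gaussian noise with sd noise_sigma·D0."""
    if d0 <= 0:
        raise ValueError("D0 must be positive")
    rng = np.random.default_rng(seed)
    c = np.asarray(conc_grid, dtype=float)
    d = d0 * (1.0 + kd * c)
    if noise_sigma > 0:
        d = d + rng.normal(0.0, noise_sigma * d0, size=c.shape)
    truth = SimulationTruth(
        params={"D0": d0, "kD": kd, "noise_sigma": noise_sigma}, seed=seed
    )
    return ConcentrationSeries(concentrations=c, responses=d), truth


def simulate_viscosity(
    y0: float,
    k: float,
    conc_grid,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[ConcentrationSeries, SimulationTruth]:
    """η = Y0·e^(kC)·(1 + Gaussian relative noise)."""
    if y0 <= 0:
        raise ValueError("Y0 must be positive")
    rng = np.random.default_rng(seed)
    c = np.asarray(conc_grid, dtype=float)
    eta = y0 * np.exp(k * c)
    if noise_sigma > 0:
        eta = eta * (1.0 + rng.normal(0.0, noise_sigma, size=c.shape))
    truth = SimulationTruth(
        params={"Y0": y0, "k": k, "noise_sigma": noise_sigma}, seed=seed
    )
    return ConcentrationSeries(concentrations=c, responses=eta), truth


def simulate_spectrum(
    peak_nm: float,
    width_nm: float = 40.0,
    amplitude: float = 1.0,
    baseline: float = 0.05,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[SpectrumTrace, SimulationTruth]:
    """Gaussian plasmon peak on the 450–650 nm grid (1 nm spacing)."""
    if not 450.0 <= peak_nm <= 650.0:
        raise ValueError("peak must lie within the 450-650 nm window")
    rng = np.random.default_rng(seed)
    w = np.arange(450.0, 650.0 + 1.0, 1.0)
    a = baseline + amplitude * np.exp(-0.5 * ((w - peak_nm) / width_nm) ** 2)
    if noise_sigma > 0:
        a = a + rng.normal(0.0, noise_sigma * amplitude, size=w.shape)
    truth = SimulationTruth(
        params={
            "peak_nm": peak_nm, "width_nm": width_nm, "amplitude": amplitude,
            "baseline": baseline, "noise_sigma": noise_sigma,
        },
        seed=seed,
    )
    return SpectrumTrace(wavelengths=w, absorbance=a), truth


def simulate_thermogram(
    tm_list,
    widths=None,
    amplitudes=None,
    baseline: float = 0.8,
    noise_sigma: float = 0.0,
    tagg: float | None = None,
    seed: int = 0,
) -> tuple[Thermogram, SimulationTruth]:
    """Sum of logistic unfolding transitions on a 0.5 °C grid, 20–95 °C.

    Each Tm contributes amplitude/(1+exp(−(T−Tm)/width)); an optional
    scattering channel carries a single aggregation transition at ``tagg``.
    Transitions closer than their width trigger a warning since derivative
    peaks may merge.
    """
    import warnings

    tm_list = list(tm_list)
    for tm in tm_list:
        if not 20.0 < tm < 95.0:
            raise ValueError(f"Tm {tm} outside the 20-95 °C ramp")
    widths = list(widths) if widths is not None else [1.5] * len(tm_list)
    amplitudes = list(amplitudes) if amplitudes is not None else [0.1] * len(tm_list)
    for a, b, w in zip(sorted(tm_list)[:-1], sorted(tm_list)[1:], widths):
        if b - a < w:
            warnings.warn(
                f"transitions at {a} and {b} °C closer than width {w}; "
                "recovery not guaranteed",
                stacklevel=2,
            )
    rng = np.random.default_rng(seed)
    t = np.arange(20.0, 95.0 + 0.5, 0.5)
    ratio = np.full_like(t, baseline)
    for tm, width, amp in zip(tm_list, widths, amplitudes):
        ratio = ratio + amp / (1.0 + np.exp(-(t - tm) / width))
    if noise_sigma > 0:
        ratio = ratio + rng.normal(0.0, noise_sigma, size=t.shape)
    scattering = None
    if tagg is not None:
        scattering = 1.0 / (1.0 + np.exp(-(t - tagg) / 1.5))
        if noise_sigma > 0:
            scattering = scattering + rng.normal(0.0, noise_sigma, size=t.shape)
    truth = SimulationTruth(
        params={
            "Tm_list": tm_list, "widths": widths, "amplitudes": amplitudes,
            "baseline": baseline, "noise_sigma": noise_sigma, "Tagg": tagg,
        },
        seed=seed,
    )
    return Thermogram(temperature=t, ratio_350_330=ratio, scattering=scattering), truth
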