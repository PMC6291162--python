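"""Synthetic inputs with the statistical structure the analyses assume.

Every generator is a pure function of its configuration and a root seed.
The root seed is fanned out per generator through fixed stream
identifiers (``default_rng([seed, stream])``), so adding a new generator
never perturbs the draws of an existing one.

Defaults mirror the study conditions the analyses were built for: a
16,086-proband screened cohort, a per-chromosome de novo rate of
6.16e-6, a 206-residue protein with a 24-residue binding region, 34
variant-bearing residues outside the region, and triplicate plate wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assay_norm import PlateAssay, Well
from .cohort_io import CohortTable, ProteinVariant, format_protein_change
from .structure_contacts import RegionAnnotation

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "simulate_population_variants",
    "simulate_structure",
    "simulate_assay",
    "default_region",
]

# fixed PRNG stream identifiers, one per generator
_STREAM_COHORT = 1
_STREAM_POPULATION = 2
_STREAM_STRUCTURE = 3
_STREAM_ASSAY = 4

_AA = "ACDEFGHIKLMNPQRSTVWY"

#: default assay groups: (mean, sd) per construct on the raw-signal scale.
#: GTPase wells measure remaining GTP (NTC maximal); binding wells measure
#: effector capture (NTC minimal). Triplicates, as in a typical plate run.
DEFAULT_GTPASE_GROUPS = {
    "NTC": (100.0, 3.0),
    "WT": (20.0, 3.0),       # robust hydrolysis: little GTP remains
    "G23D": (90.0, 3.0),     # hydrolysis-dead control
    "V25M": (88.0, 3.0),
    "D130G": (85.0, 3.0),
}
DEFAULT_GLISA_GROUPS = {
    "NTC": (0.20, 0.01),
    "WT": (0.60, 0.03),
    "G23D": (1.20, 0.05),    # ~2-fold increased binding vs WT
    "V25M": (0.25, 0.02),    # 2-5-fold reduced binding
    "D130G": (0.22, 0.02),
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs for the synthetic generators (see module docstring)."""

    seed: int = 0
    # cohort
    n_probands: int = 16_086
    denovo_rate: float = 6.16e-6
    hotspot_codons: tuple[int, ...] = ()
    hotspot_prob: float = 0.0
    phenotype_prevalence: dict = field(default_factory=dict)
    n_monozygotic_sets: int = 0
    gene_symbol: str = "GENE"
    # protein / region
    protein_length: int = 206
    region_residues: tuple[int, ...] = ()
    region_size: int = 24
    depletion_factor: float = 0.0
    n_population_variant_residues: int = 34
    # structure geometry
    residue_spacing: float = 6.0
    contact_fraction: float = 0.7   # contact distance as fraction of threshold
    min_atom_separation: float = 0.8
    # assay
    gtpase_groups: dict = field(default_factory=lambda: dict(DEFAULT_GTPASE_GROUPS))
    glisa_groups: dict = field(default_factory=lambda: dict(DEFAULT_GLISA_GROUPS))
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.denovo_rate <= 1.0:
            raise ValueError("denovo_rate must be a probability")
        if self.depletion_factor < 0:
            raise ValueError("depletion_factor must be >= 0")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def default_region(config: SimulationConfig) -> frozenset[int]:
    """The configured region, or the first ``region_size`` residues spaced
    evenly across the protein when no explicit set is given."""
    if config.region_residues:
        return frozenset(int(r) for r in config.region_residues)
    idx = np.linspace(1, config.protein_length, num=config.region_size)
    return frozenset(int(round(i)) for i in idx)


def simulate_cohort(config: SimulationConfig) -> CohortTable:
    """Draw a cohort under the mutation-rate null (plus optional hotspots).

    The number of de novo alleles is Binomial(2 * n_probands, rate). Each
    allele is assigned to a codon — uniformly, or to a hotspot codon with
    probability ``hotspot_prob`` — and becomes a missense variant in its
    own proband/family. Monozygotic duplicate probands can be injected;
    phenotype flags are sampled per configured prevalence.
    """
    rng = _rng(config, _STREAM_COHORT)
    n_alleles = int(rng.binomial(2 * config.n_probands, config.denovo_rate))
    probands, variants = [], []
    for i in range(n_alleles):
        pid, fam = f"SIM{i + 1}", f"SIMF{i + 1}"
        codon = _draw_codon(rng, config)
        ref = _AA[rng.integers(len(_AA))]
        alt = _AA[rng.integers(len(_AA))]
        while alt == ref:
            alt = _AA[rng.integers(len(_AA))]
        pchange = format_protein_change(ref, codon, alt)
        member_ids = [pid]
        mz_id = None
        if i < config.n_monozygotic_sets:
            mz_id = f"SIMMZ{i + 1}"
            member_ids.append(f"{pid}b")
        for member in member_ids:
            phenos = {
                flag: ("present" if rng.random() < prev else "absent")
                for flag, prev in config.phenotype_prevalence.items()
            }
            probands.append(
                {"proband_id": member, "family_id": fam,
                 "monozygotic_set_id": mz_id, "phenotypes": phenos}
            )
            variants.append(
                ProteinVariant(
                    gene_symbol=config.gene_symbol,
                    transcript_id="SIM_TX",
                    cdna_change=f"c.{codon * 3}N>N",
                    protein_change=pchange,
                    ref_residue=ref,
                    codon_index=codon,
                    alt_residue=alt,
                    consequence="missense",
                    inheritance="de_novo",
                    proband_id=member,
                    family_id=fam,
                    site="SIM",
                )
            )
    return CohortTable(probands=probands, variants=variants)


def _draw_codon(rng: np.random.Generator, config: SimulationConfig) -> int:
    if config.hotspot_codons and rng.random() < config.hotspot_prob:
        return int(config.hotspot_codons[rng.integers(len(config.hotspot_codons))])
    return int(rng.integers(1, config.protein_length + 1))


def simulate_population_variants(config: SimulationConfig) -> set[int]:
    """Place variant-bearing residues with region odds scaled by the
    depletion factor.

    ``depletion_factor`` multiplies each in-region residue's selection
    weight: 0 reproduces absolute depletion, 1 is the uniform null.
    """
    region = default_region(config)
    if not region <= set(range(1, config.protein_length + 1)):
        raise ValueError("region residues outside the protein")
    rng = _rng(config, _STREAM_POPULATION)
    residues = np.arange(1, config.protein_length + 1)
    weights = np.where(np.isin(residues, sorted(region)),
                       config.depletion_factor, 1.0)
    n = config.n_population_variant_residues
    positive = int((weights > 0).sum())
    if n > positive:
        raise ValueError(
            f"cannot place {n} variant residues on {positive} "
            "residues with positive weight"
        )
    chosen = rng.choice(residues, size=n, replace=False,
                        p=weights / weights.sum())
    return {int(r) for r in chosen}


def simulate_structure(
    config: SimulationConfig,
    n_residues: int,
    declared_contacts: frozenset[int] | set[int],
    threshold: float,
    path: str | Path,
    ligand_code: str = "GDP",
) -> tuple[Path, frozenset[int]]:
    """Write a synthetic PDB whose ligand contacts are known by construction.

    Protein residues (CA + CB pseudo-atoms) sit on a straight backbone
    with ``residue_spacing`` Å between CA atoms; one ligand atom is
    placed opposite each declared contact residue at a randomized
    distance strictly inside the threshold. All other residues are at
    least one backbone spacing away from every ligand atom. A random
    rigid rotation + translation is applied to the whole system so the
    coordinates are not axis-aligned. Returns the output path and the
    declared ground-truth contact set.
    """
    declared = frozenset(int(r) for r in declared_contacts)
    if not declared <= set(range(1, n_residues + 1)):
        raise ValueError("declared contacts outside [1, n_residues]")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if config.residue_spacing <= threshold:
        raise ValueError(
            "residue spacing must exceed the threshold for unambiguous "
            "ground truth"
        )
    rng = _rng(config, _STREAM_STRUCTURE)
    coords, names, resids, het = [], [], [], []
    for i in range(1, n_residues + 1):
        x = i * config.residue_spacing
        coords.append((x, 0.0, 0.0)); names.append("CA"); resids.append(i); het.append(False)
        coords.append((x, -1.5, 0.0)); names.append("CB"); resids.append(i); het.append(False)
    d_max = threshold * config.contact_fraction
    if declared and d_max < config.min_atom_separation:
        raise ValueError(
            f"maximal contact distance {d_max:.2f} Å is below the atomic "
            f"overlap limit {config.min_atom_separation} Å; increase the "
            "threshold"
        )
    d_min = max(config.min_atom_separation, 0.4 * threshold)
    for j, r in enumerate(sorted(declared), start=1):
        d = rng.uniform(d_min, max(d_min + 1e-6, d_max))
        coords.append((r * config.residue_spacing, d, 0.0))
        names.append(f"P{j}" if j < 10 else f"Q{j - 9}")
        resids.append(900); het.append(True)
    xyz = np.asarray(coords)
    # random rigid motion (rotation from QR of a Gaussian matrix)
    q, rmat = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(rmat))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    xyz = xyz @ q.T + rng.uniform(-20, 20, size=3)
    path = Path(path)
    lines = []
    serial = 0
    for (x, y, z), name, resid, is_het in zip(xyz, names, resids, het):
        serial += 1
        record = "HETATM" if is_het else "ATOM  "
        resname = ligand_code if is_het else "GLY"
        chain = "B" if is_het else "A"
        element = name[0]
        lines.append(
            f"{record}{serial:5d} {name:<4s} {resname:>3s} {chain}"
            f"{resid:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {element:>2s}\n"
        )
    lines.append("END\n")
    path.write_text("".join(lines), encoding="utf-8")
    return path, declared


def simulate_assay(config: SimulationConfig, assay_type: str = "gtpase_luminescence") -> PlateAssay:
    """Draw replicate well signals ~ Normal(group mean, sd), truncated at 0."""
    groups = (config.gtpase_groups if assay_type == "gtpase_luminescence"
              else config.glisa_groups)
    rng = _rng(config, _STREAM_ASSAY)
    wells = []
    for construct, (mean, sd) in groups.items():
        draws = rng.normal(mean, sd, size=config.n_replicates)
        for rep, value in enumerate(draws, start=1):
            wells.append(
                Well(construct=construct, replicate=rep,
                     signal=max(0.0, float(value)), assay_type=assay_type)
            )
    return PlateAssay(wells=wells)
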