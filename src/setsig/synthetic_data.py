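"""Synthetic inputs with planted ground truth for every pipeline stage.

Every generator is a pure function of a :class:`PlantedDesign` (which fixes
the seed) and emits its ground truth alongside the data, so downstream
recovery tests never have to re-infer what was planted.  The default design
mirrors the scales of the real analyses the pipeline was built for: a
20,438-gene coding universe, a ~5,000-gene differential-expression list, a
~1,000-gene disease risk set, and regulator/mark libraries of a few hundred
targets per set.

Planting strength is expressed as a target odds ratio and converted to a
per-gene sampling probability: if a fraction p0 of the relevant pool is
"disease", planting at odds ratio OR samples disease genes with probability
q = OR·p0 / (1 − p0 + OR·p0), i.e. the planted odds q/(1−q) are OR times
the baseline odds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .assay_scores import ArenaGeometry, Trajectory
from .enrich import ContingencyTable, odds_ratio
from .genesets import GeneSet, GeneSetLibrary, write_gmt, write_gene_list
from .peakmap import GeneModel, GeneRecord, Peak, PeakSet, write_bed, write_genes_bed6

__all__ = [
    "PlantedDesign",
    "planting_probability",
    "make_universe",
    "make_disease_and_test_sets",
    "make_regulator_library",
    "make_histone_libraries",
    "make_peaks",
    "make_trajectory",
    "make_signature_benchmark",
    "default_arena",
    "simulate_all",
]


@dataclass(frozen=True)
class PlantedDesign:
    """Knobs of the synthetic study, all with planted, recoverable truth.

    Defaults emulate the real analysis scales: 20,438 coding genes, a
    5,044-gene test list, a 1,000-gene disease set, and a planted overlap
    of 390 genes, which corresponds to a design odds ratio of ~2.
    """

    universe_size: int = 20438
    disease_set_size: int = 1000
    test_set_size: int = 5044
    planted_overlap: int = 390
    n_regulators: int = 100
    targets_per_regulator: int = 300
    shared_regulators: int = 5
    colocalization_fraction: float = 0.8
    preference_p: float = 0.5
    planting_or: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.universe_size < 1:
            raise ValueError("universe_size must be >= 1")
        if self.planted_overlap > min(self.disease_set_size, self.test_set_size):
            raise ValueError("planted_overlap exceeds a set size")
        if self.disease_set_size > self.universe_size:
            raise ValueError("disease set larger than universe")
        if self.test_set_size - self.planted_overlap > self.universe_size - self.disease_set_size:
            raise ValueError("test set does not fit outside the disease set")
        for r in (self.colocalization_fraction, self.preference_p):
            if not (0.0 <= r <= 1.0):
                raise ValueError("ratios must lie in [0, 1]")
        if self.shared_regulators > self.n_regulators:
            raise ValueError("shared_regulators exceeds n_regulators")
        if self.planting_or <= 0:
            raise ValueError("planting_or must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlantedDesign":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**cfg)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def planting_probability(or_target: float, baseline_frac: float) -> float:
    """Sampling probability whose odds are ``or_target`` times the baseline odds."""
    if not (0.0 < baseline_frac < 1.0):
        raise ValueError("baseline_frac must lie strictly in (0, 1)")
    p0 = baseline_frac
    return or_target * p0 / (1.0 - p0 + or_target * p0)


def _symbols(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def _rng(design_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([design_seed, stream])


def make_universe(n: int, seed: int = 0) -> GeneSet:
    """Synthetic gene universe of ``n`` symbols G000001..; deterministic."""
    if n < 1:
        raise ValueError("universe must contain at least one gene")
    return GeneSet(name=f"universe_{n}", genes=frozenset(_symbols(n)))


def _draw_disease(design: PlantedDesign) -> frozenset[str]:
    rng = _rng(design.seed, 1)
    uni = _symbols(design.universe_size)
    idx = rng.choice(design.universe_size, size=design.disease_set_size, replace=False)
    return frozenset(uni[i] for i in idx)


def make_disease_and_test_sets(
    design: PlantedDesign,
) -> tuple[GeneSet, GeneSet, dict]:
    """Disease set plus a test set with a planted overlap.

    The disease set is uniform over the universe; the test set takes exactly
    ``planted_overlap`` genes from it and the remainder from outside it, so
    the 2x2 table — and hence the design odds ratio — is known exactly.
    """
    rng = _rng(design.seed, 2)
    uni = _symbols(design.universe_size)
    disease = _draw_disease(design)
    dis_sorted = sorted(disease)
    rest = sorted(set(uni) - disease)
    overlap_idx = rng.choice(len(dis_sorted), size=design.planted_overlap, replace=False)
    extra_idx = rng.choice(
        len(rest), size=design.test_set_size - design.planted_overlap, replace=False
    )
    test_genes = frozenset(
        [dis_sorted[i] for i in overlap_idx] + [rest[i] for i in extra_idx]
    )
    a = design.planted_overlap
    table = ContingencyTable(
        a,
        design.test_set_size - a,
        design.disease_set_size - a,
        design.universe_size - design.test_set_size - design.disease_set_size + a,
    )
    truth = {
        "planted_overlap": a,
        "design_odds_ratio": odds_ratio(table),
        "table": (table.a, table.b, table.c, table.d),
    }
    return (
        GeneSet(name="DISEASE_SYN", genes=disease),
        GeneSet(name="TEST_SYN", genes=test_genes),
        truth,
    )


def _planted_set(
    rng: np.random.Generator,
    size: int,
    pool_preferred: Sequence[str],
    pool_other: Sequence[str],
    q: float,
) -> frozenset[str]:
    """Draw ``size`` genes, each taken from the preferred pool with probability q."""
    n_pref = min(int(rng.binomial(size, q)), len(pool_preferred), size)
    pref_idx = rng.choice(len(pool_preferred), size=n_pref, replace=False)
    other_idx = rng.choice(len(pool_other), size=size - n_pref, replace=False)
    return frozenset(
        [pool_preferred[i] for i in pref_idx] + [pool_other[i] for i in other_idx]
    )


def make_regulator_library(
    design: PlantedDesign,
) -> tuple[GeneSetLibrary, dict]:
    """ChIP-derived-style regulator library with planted disease targeting.

    ``shared_regulators`` of the ``n_regulators`` sets draw their targets
    preferentially from the disease set at the design's planting odds ratio;
    the rest are uniform.  Ground truth carries the planted regulator names
    and every regulator's target set.
    """
    rng = _rng(design.seed, 3)
    disease = sorted(_draw_disease(design))
    other = sorted(set(_symbols(design.universe_size)) - set(disease))
    q = planting_probability(
        design.planting_or, design.disease_set_size / design.universe_size
    )
    sets = []
    targets_truth = {}
    planted_names = [f"REG{i:03d}" for i in range(1, design.shared_regulators + 1)]
    for i in range(1, design.n_regulators + 1):
        name = f"REG{i:03d}"
        if name in planted_names:
            genes = _planted_set(rng, design.targets_per_regulator, disease, other, q)
        else:
            uni = _symbols(design.universe_size)
            idx = rng.choice(len(uni), size=design.targets_per_regulator, replace=False)
            genes = frozenset(uni[j] for j in idx)
        sets.append(GeneSet(name=name, description="synthetic regulator", genes=genes))
        targets_truth[name] = sorted(genes)
    library = GeneSetLibrary(name="CHIPX_SYN", sets=sets)
    truth = {"planted_regulators": planted_names, "q": q, "targets": targets_truth}
    return library, truth


DEFAULT_MARKS = ("H3K27me3", "H3K4me3", "H3K9me3", "H3K27ac")


def make_histone_libraries(
    design: PlantedDesign,
    marks: Sequence[str] = DEFAULT_MARKS,
    sets_per_mark: int = 8,
    genes_per_set: int = 300,
    target_mark: str = "H3K27me3",
) -> tuple[GeneSetLibrary, GeneSetLibrary, dict]:
    """Two histone-mark libraries (ENCODE-like and Roadmap-like).

    Each library holds ``sets_per_mark`` query sets per mark, named
    ``"<mark> tissueNN synK"`` so the default mark tokenizer parses them.
    Target-mark sets draw genes preferentially from the disease set at the
    design's planting odds ratio; all other sets are uniform.
    """
    if target_mark not in marks:
        raise ValueError(f"target mark {target_mark!r} not among marks")
    rng = _rng(design.seed, 4)
    disease = sorted(_draw_disease(design))
    uni = _symbols(design.universe_size)
    other = sorted(set(uni) - set(disease))
    q = planting_probability(
        design.planting_or, design.disease_set_size / design.universe_size
    )
    libraries = []
    for k, lib_name in enumerate(("ENCODE_HM_SYN", "ROADMAP_HM_SYN")):
        sets = []
        for mark in marks:
            for j in range(1, sets_per_mark + 1):
                name = f"{mark} tissue{j:02d} syn{k}"
                if mark == target_mark:
                    genes = _planted_set(rng, genes_per_set, disease, other, q)
                else:
                    idx = rng.choice(len(uni), size=genes_per_set, replace=False)
                    genes = frozenset(uni[i] for i in idx)
                sets.append(
                    GeneSet(name=name, description="synthetic mark set", genes=genes)
                )
        libraries.append(GeneSetLibrary(name=lib_name, sets=sets))
    truth = {"target_mark": target_mark, "q": q, "disease_genes": disease}
    return libraries[0], libraries[1], truth


def make_peaks(
    design: PlantedDesign,
    genome_length: int = 100_000_000,
    n_peaks: int = 1000,
    n_genes: int = 5000,
    peak_width: int = 200,
    gene_length: int = 2000,
) -> tuple[PeakSet, PeakSet, GeneModel, dict]:
    """Two peak sets with planted colocalization, plus a gene model.

    A fraction ``colocalization_fraction`` of set A's peaks is placed to
    overlap a B peak at a gene promoter, and those colocalized promoters are
    biased toward disease genes at the design's planting odds ratio.
    Non-colocalized A peaks sit at promoters of other genes, with one gene
    per A peak and B kept off those promoters, so the realized overlap
    fraction equals the planted fraction exactly.  B's remaining peaks are
    intergenic.
    """
    if n_peaks > n_genes:
        raise ValueError("need at least one gene per peak (n_peaks <= n_genes)")
    if n_genes > design.universe_size:
        raise ValueError("n_genes exceeds the universe size")
    spacing = genome_length // n_genes
    if spacing < gene_length + 4 * peak_width + 3000:
        raise ValueError("genome too short to pack genes without promoter collisions")
    rng = _rng(design.seed, 5)
    disease = _draw_disease(design)
    uni = _symbols(design.universe_size)
    idx = rng.choice(design.universe_size, size=n_genes, replace=False)
    model_names = [uni[i] for i in idx]
    strands = rng.choice(["+", "-"], size=n_genes)
    records = []
    for i, (name, strand) in enumerate(zip(model_names, strands)):
        start = i * spacing + 2000
        records.append(
            GeneRecord(chrom="chr1", start=start, end=start + gene_length,
                       name=name, strand=str(strand))
        )
    genes = GeneModel(records=records)
    by_name = {r.name: r for r in records}

    dis_in_model = sorted(n for n in model_names if n in disease)
    other_in_model = sorted(n for n in model_names if n not in disease)
    n_coloc = round(design.colocalization_fraction * n_peaks)
    q = planting_probability(design.planting_or, len(dis_in_model) / n_genes)
    n_coloc_dis = min(round(q * n_coloc), len(dis_in_model), n_coloc)

    dis_pick = rng.choice(len(dis_in_model), size=n_coloc_dis, replace=False)
    oth_needed = (n_coloc - n_coloc_dis) + (n_peaks - n_coloc)
    oth_pick = rng.choice(len(other_in_model), size=oth_needed, replace=False)
    coloc_genes = [dis_in_model[i] for i in dis_pick] + [
        other_in_model[i] for i in oth_pick[: n_coloc - n_coloc_dis]
    ]
    noncoloc_genes = [other_in_model[i] for i in oth_pick[n_coloc - n_coloc_dis:]]

    def promoter_anchor(rec: GeneRecord) -> int:
        # a point safely inside the promoter window, on the upstream side
        return rec.tss - 500 if rec.strand == "+" else rec.tss + 300

    a_peaks, b_peaks = [], []
    for g in coloc_genes:
        anchor = promoter_anchor(by_name[g])
        a_peaks.append(Peak("chr1", anchor, anchor + peak_width))
        # offset by half a width: overlaps A and still inside the promoter
        b_peaks.append(Peak("chr1", anchor + peak_width // 2,
                            anchor + peak_width // 2 + peak_width))
    for g in noncoloc_genes:
        anchor = promoter_anchor(by_name[g])
        a_peaks.append(Peak("chr1", anchor, anchor + peak_width))
    # B's own non-shared peaks go intergenic, far from any promoter window
    for i in range(n_peaks - n_coloc):
        pos = (i % n_genes) * spacing + 2000 + gene_length + 2 * peak_width + 1600
        b_peaks.append(Peak("chr1", pos, pos + peak_width))

    a = PeakSet(name="FACTOR_A_SYN", peaks=a_peaks)
    b = PeakSet(name="FACTOR_B_SYN", peaks=b_peaks)
    truth = {
        "colocalization_fraction": n_coloc / n_peaks,
        "n_colocalized": n_coloc,
        "q": q,
        "colocalized_genes": sorted(coloc_genes),
        "noncolocalized_genes": sorted(noncoloc_genes),
        "disease_genes_in_model": dis_in_model,
    }
    return a, b, genes, truth


def default_arena(chamber_length: float = 60.0) -> ArenaGeometry:
    """Test-chamber geometry: social wall at +L/2, empty wall at −L/2 (mm)."""
    half = chamber_length / 2.0
    return ArenaGeometry(y_social=half, y_empty=-half)


def make_trajectory(
    n_frames: int,
    preference_p: float,
    arena: ArenaGeometry,
    seed: int,
    frame_rate: float = 7.5,
    step_sigma: float = 2.0,
    drift_max: float = 1.5,
    x_halfwidth: float = 4.0,
) -> Trajectory:
    """Bounded random walk with drift toward the social wall.

    Per frame the y position takes a Gaussian step (SD ``step_sigma``) plus a
    drift of ``preference_p × drift_max`` toward the social wall, reflecting
    at both walls; ``preference_p = 0`` gives a symmetric walk.  x jitters
    within the chamber width.  Units are arena length units per frame.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not (0.0 <= preference_p <= 1.0):
        raise ValueError("preference_p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lo = min(arena.y_social, arena.y_empty)
    hi = max(arena.y_social, arena.y_empty)
    toward = 1.0 if arena.y_social > arena.y_empty else -1.0
    drift = toward * preference_p * drift_max
    steps = rng.normal(loc=drift, scale=step_sigma, size=n_frames)
    x = np.clip(rng.normal(0.0, 1.0, size=n_frames).cumsum() * 0.2,
                -x_halfwidth, x_halfwidth)
    y = np.empty(n_frames)
    pos = (lo + hi) / 2.0
    span = hi - lo
    for i in range(n_frames):
        pos += steps[i]
        # reflect until inside (steps are small relative to the chamber)
        while pos < lo or pos > hi:
            if pos < lo:
                pos = 2 * lo - pos
            else:
                pos = 2 * hi - pos
        y[i] = pos
    return Trajectory(frames=np.column_stack([x, y]), frame_rate=frame_rate)


def make_signature_benchmark(
    design: PlantedDesign,
    n_decoys: int = 55,
    set_size: int = 400,
    planted_fraction: float = 0.5,
    seed: int | None = None,
) -> dict:
    """Joint construction for signature-recovery experiments.

    Builds one regulator library (uniform targets), then gene sets driven by
    regulator groups: a "disease" set and a sibling set share the same
    planted group of ``design.shared_regulators`` regulators (each draws
    ``planted_fraction`` of its genes from the group's pooled targets),
    while every decoy set gets its own group drawn from the remaining
    regulators.  Ground truth names the planted group and each decoy's
    group.
    """
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng([seed, 6])
    uni = _symbols(design.universe_size)
    n_reg = design.n_regulators
    reg_names = [f"REG{i:03d}" for i in range(1, n_reg + 1)]
    targets: dict[str, list[str]] = {}
    sets = []
    for name in reg_names:
        idx = rng.choice(design.universe_size, size=design.targets_per_regulator,
                         replace=False)
        tg = [uni[i] for i in idx]
        targets[name] = tg
        sets.append(GeneSet(name=name, description="synthetic regulator",
                            genes=frozenset(tg)))
    library = GeneSetLibrary(name="CHIPX_SYN", sets=sets)

    g = design.shared_regulators
    planted = list(rng.choice(reg_names, size=g, replace=False))
    non_planted = [r for r in reg_names if r not in planted]

    def driven_set(name: str, group: list[str]) -> GeneSet:
        pool = sorted({t for r in group for t in targets[r]})
        rest = sorted(set(uni) - set(pool))
        genes = _planted_set(rng, set_size, pool, rest, planted_fraction)
        return GeneSet(name=name, description="regulator-driven synthetic set",
                       genes=genes)

    disease = driven_set("DISEASE_SYN", planted)
    sibling = driven_set("SIBLING_SYN", planted)
    decoy_groups = {}
    decoys = []
    for i in range(1, n_decoys + 1):
        group = list(rng.choice(non_planted, size=min(g, len(non_planted)),
                                replace=False))
        name = f"DECOY{i:03d}"
        decoy_groups[name] = group
        decoys.append(driven_set(name, group))
    return {
        "library": library,
        "disease": disease,
        "sibling": sibling,
        "decoys": decoys,
        "truth": {"planted_regulators": planted, "decoy_groups": decoy_groups},
    }


def simulate_all(design: PlantedDesign, outdir: str | Path) -> dict:
    """Write a full fixture directory: GMT, gene lists, BED, CSV + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    disease, test, truth_sets = make_disease_and_test_sets(design)
    reg_lib, truth_reg = make_regulator_library(design)
    hm1, hm2, truth_hm = make_histone_libraries(design)
    n_genes = min(5000, design.universe_size)
    a, b, genes, truth_peaks = make_peaks(
        design, n_peaks=min(1000, n_genes), n_genes=n_genes
    )
    arena = default_arena()
    traj = make_trajectory(4500, design.preference_p, arena, seed=design.seed)

    write_gene_list(disease.genes, outdir / "disease_genes.txt")
    write_gene_list(test.genes, outdir / "test_genes.txt")
    write_gmt(reg_lib, outdir / "regulators.gmt")
    write_gmt(hm1, outdir / "encode_hm.gmt")
    write_gmt(hm2, outdir / "roadmap_hm.gmt")
    write_bed(a, outdir / "factor_a.bed")
    write_bed(b, outdir / "factor_b.bed")
    write_genes_bed6(genes, outdir / "genes.bed")
    traj.to_csv(outdir / "trajectory.csv")
    (outdir / "arena.yaml").write_text(
        yaml.safe_dump({"y_social": arena.y_social, "y_empty": arena.y_empty})
    )
    manifest = {
        "design": design.to_dict(),
        "sets": truth_sets,
        "regulators": {k: truth_reg[k] for k in ("planted_regulators", "q")},
        "histone": {k: truth_hm[k] for k in ("target_mark", "q")},
        "peaks": {k: truth_peaks[k] for k in
                  ("colocalization_fraction", "n_colocalized", "q")},
    }
    (outdir / "ground_truth.json").write_text(json.dumps(manifest, indent=2))
    return manifest
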