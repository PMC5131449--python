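"""Synthetic 4C-seq study generator with known ground truth.

Real 4C coverage profiles show near-complete fragend coverage around the
viewpoint that decays with genomic distance, sparse background coverage
elsewhere, and dense patches at loci in physical contact with the
viewpoint. The generator reproduces exactly that structure: each usable
fragend is an independent Bernoulli draw with success probability

    max(background, 2^(-d / halflife), planted contact probability)

where d is the fragend's distance to the viewpoint and the planted term
applies inside configured contact intervals. Taking the max keeps every
fragend a single draw. Alongside coverage it emits every annotation the
candidate-gene filter consumes (TSS table, H3K27ac and CTCF peaks, LD
variants, expression, eQTL and ranked differential-expression tables),
with the planted truth recorded for parameter-recovery tests.

Randomness is organised as one global seed fanned out into named
substreams (genome per chromosome, coverage per viewpoint x cell type), so
adding a viewpoint or cell type never perturbs the data of the others.
"""
from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragends import (
    CoverageProfile,
    FragendLibrary,
    ViewpointSpec,
    build_fragend_library,
)

__all__ = [
    "PlantedContact",
    "SimConfig",
    "GroundTruth",
    "Study",
    "generate_genome",
    "simulate_coverage",
    "emit_reads",
    "generate_annotations",
    "simulate_study",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _substream(seed: int, *keys) -> np.random.Generator:
    """Named, order-independent substream of a global seed."""
    spawn = tuple(zlib.crc32(str(k).encode()) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=spawn))


@dataclass(frozen=True)
class PlantedContact:
    """A distal region in contact with a viewpoint, with elevated coverage."""

    chrom: str
    start: int
    end: int
    prob: float

    def __post_init__(self) -> None:
        if not (0.0 < self.prob < 1.0):
            raise ValueError("contact coverage probability must be in (0,1)")
        if self.start < 0 or self.end <= self.start:
            raise ValueError("contact interval must be non-empty and non-negative")


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    gatc_density is the expected number of GATC sites per kbp (random
    sequence has ~3.9/kbp; the default matches that). background_coverage
    is the per-fragend probability of spurious coverage far from the
    viewpoint; viewpoint_decay_halflife (bp) sets how fast near-viewpoint
    coverage decays (a modelling choice -- see docs/methods.md).
    """

    seed: int = 0
    n_chromosomes: int = 1
    chromosome_length: int = 1_000_000
    gatc_density: float = 4.0
    background_coverage: float = 0.05
    viewpoint_decay_halflife: int = 20_000
    planted_contacts: list[PlantedContact] = field(default_factory=list)
    n_viewpoints: int = 1
    n_cell_types: int = 1

    def __post_init__(self) -> None:
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be positive")
        if self.n_chromosomes <= 0:
            raise ValueError("n_chromosomes must be positive")
        if not (0.0 < self.background_coverage < 1.0):
            raise ValueError("background_coverage must be in (0,1)")
        if self.gatc_density < 0:
            raise ValueError("gatc_density must be non-negative")
        if self.viewpoint_decay_halflife <= 0:
            raise ValueError("viewpoint_decay_halflife must be positive")
        for c in self.planted_contacts:
            if c.end > self.chromosome_length:
                raise ValueError(f"planted contact {c} exceeds chromosome bounds")
            if c.prob <= self.background_coverage:
                raise ValueError(
                    "planted contact probability must exceed background coverage"
                )


@dataclass
class GroundTruth:
    """What was planted: contacts per viewpoint, true target genes, and the
    expression / locus-activity classes used to build the annotations."""

    planted: dict[str, list[PlantedContact]] = field(default_factory=dict)
    targets: dict[str, list[str]] = field(default_factory=dict)
    expressed: dict[str, set[str]] = field(default_factory=dict)  # cell type -> genes
    active: dict[str, set[str]] = field(default_factory=dict)     # cell type -> SNPs

    @property
    def all_targets(self) -> set[str]:
        return set().union(*self.targets.values()) if self.targets else set()


@dataclass
class Study:
    """A complete synthetic study: inputs plus ground truth."""

    config: SimConfig
    genome: dict[str, str]
    library: FragendLibrary
    viewpoints: list[ViewpointSpec]
    cell_types: list[str]
    profiles: dict[tuple[str, str], CoverageProfile]  # (snp_id, cell type)
    truth: GroundTruth
    genes: pd.DataFrame
    peaks: dict[str, pd.DataFrame]  # H3K27ac per cell type
    ctcf: pd.DataFrame
    ld: pd.DataFrame
    expression: dict[str, pd.DataFrame]
    eqtl: pd.DataFrame
    ranked_de: pd.DataFrame
    known_genes: set[str]


def _scrub_gatc(data: bytes) -> bytes:
    """Remove every GATC occurrence by overwriting it with AAAA.

    GATC occurrences cannot overlap each other, and AAAA cannot complete a
    new GATC across a replacement boundary, so one pass leaves the
    sequence GATC-free.
    """
    return re.sub(b"GATC", b"AAAA", data)


def generate_genome(config: SimConfig) -> dict[str, str]:
    """Toy genome with a controllable GATC site count.

    Sites are placed explicitly (Poisson count at gatc_density per kbp,
    uniform positions with >= 4 bp spacing) into background sequence that
    is scrubbed GATC-free, so with gatc_density=0 the residual GATC rate
    is exactly zero and the realised site count is the planted count.
    """
    genome: dict[str, str] = {}
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        rng = _substream(config.seed, "genome", ci)
        L = config.chromosome_length
        arr = bytearray(_scrub_gatc(_BASES[rng.integers(0, 4, size=L)].tobytes()))
        n_sites = rng.poisson(L * config.gatc_density / 1000.0)
        if n_sites > 0:
            pos = np.sort(rng.choice(max(L - 4, 1), size=min(n_sites, L // 8), replace=False))
            keep = np.concatenate([[True], np.diff(pos) >= 4])
            for p in pos[keep]:
                arr[p : p + 4] = b"GATC"
        genome[chrom] = arr.decode("ascii")
    return genome


def coverage_probability(
    midpoints: np.ndarray,
    viewpoint: ViewpointSpec,
    config: SimConfig,
    planted: list[PlantedContact] | None = None,
) -> np.ndarray:
    """Per-fragend Bernoulli success probability of the coverage model."""
    planted = config.planted_contacts if planted is None else planted
    d = np.abs(midpoints - viewpoint.position).astype(float)
    decay = np.exp2(-d / config.viewpoint_decay_halflife)
    p = np.maximum(config.background_coverage, decay)
    for c in planted:
        if c.chrom != viewpoint.chrom:
            continue
        inside = (midpoints >= c.start) & (midpoints < c.end)
        p = np.where(inside, np.maximum(p, c.prob), p)
    return p


def simulate_coverage(
    library: FragendLibrary,
    viewpoint: ViewpointSpec,
    config: SimConfig,
    cell_type: str = "ct1",
    planted: list[PlantedContact] | None = None,
) -> tuple[CoverageProfile, list[PlantedContact]]:
    """Draw a binary coverage profile for one viewpoint in one cell type.

    Returns the profile and the planted contact intervals that apply to it
    (the per-viewpoint ground truth).
    """
    if viewpoint.chrom not in library.chroms:
        raise ValueError(f"viewpoint chromosome {viewpoint.chrom!r} not in library")
    if not (0 <= viewpoint.position < library.chrom_lengths[viewpoint.chrom]):
        raise ValueError(
            f"viewpoint {viewpoint.snp_id} position {viewpoint.position} outside "
            f"chromosome {viewpoint.chrom}"
        )
    usable = library.usable(viewpoint.chrom)
    mid = ((usable["start"] + usable["end"]) // 2).to_numpy()
    planted_here = [
        c
        for c in (config.planted_contacts if planted is None else planted)
        if c.chrom == viewpoint.chrom
    ]
    p = coverage_probability(mid, viewpoint, config, planted_here)
    rng = _substream(config.seed, "coverage", viewpoint.snp_id, cell_type)
    status = (rng.random(len(mid)) < p).astype(np.int64)
    profile = CoverageProfile(
        viewpoint=viewpoint,
        cell_type=cell_type,
        chrom=viewpoint.chrom,
        starts=usable["start"].to_numpy(),
        ends=usable["end"].to_numpy(),
        counts=status,
        seqs=tuple(usable["seq"]),
    )
    return profile, planted_here


def emit_reads(
    profile: CoverageProfile, viewpoint: ViewpointSpec, depth: int = 1
) -> list[tuple[str, str]]:
    """Reads implied by a coverage profile: primer + fragend 16-mer.

    Every covered fragend yields exactly ``depth`` reads; uncovered
    fragends yield none, so mapping the reads back reproduces the profile.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if profile.seqs is None:
        raise ValueError("profile carries no fragend sequences; cannot emit reads")
    reads: list[tuple[str, str]] = []
    status = profile.status
    for i, (st, seq) in enumerate(zip(status, profile.seqs)):
        if not st:
            continue
        for j in range(depth):
            reads.append(
                (
                    f"{viewpoint.snp_id}:{profile.cell_type}:fe{i}:{j}",
                    viewpoint.primer + seq,
                )
            )
    return reads


def _random_primer(rng: np.random.Generator, length: int = 20) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def generate_annotations(
    config: SimConfig,
    truth: GroundTruth,
    viewpoints: list[ViewpointSpec],
    cell_types: list[str],
    chrom_lengths: dict[str, int],
    activity_fraction: float = 1.0,
    decoys_per_viewpoint: int = 3,
    decoy_margin_vp: int = 150_000,
    decoy_margin_contact: int = 20_000,
    expressed_target_fraction: float = 1.0,
    eqtl_fraction: float = 1.0,
    known_fraction: float = 0.0,
    n_ctcf_per_chrom: int = 20,
) -> dict:
    """Build every annotation table the candidate-gene filter needs.

    Target genes get a TSS at the centre of each planted contact; decoy
    genes are placed away from viewpoints, contacts and each other so the
    strong-effect fixture has an unambiguous expected candidate set.
    Expression values span the log2(RPKM) = -0.5 boundary by construction.
    """
    rng = _substream(config.seed, "annotations")
    gene_rows: list[tuple] = []
    gid = 0
    for vp in viewpoints:
        for c in truth.planted.get(vp.snp_id, []):
            gid += 1
            gene = f"G{gid:04d}"
            gene_rows.append((gene, c.chrom, (c.start + c.end) // 2, "+", True, vp.snp_id))
            truth.targets.setdefault(vp.snp_id, []).append(gene)
    forbidden: dict[str, list[tuple[int, int]]] = {}
    for vp in viewpoints:
        forbidden.setdefault(vp.chrom, []).append(
            (vp.position - decoy_margin_vp, vp.position + decoy_margin_vp)
        )
    for contacts in truth.planted.values():
        for c in contacts:
            forbidden.setdefault(c.chrom, []).append(
                (c.start - decoy_margin_contact, c.end + decoy_margin_contact)
            )
    for vp in viewpoints:
        L = chrom_lengths[vp.chrom]
        placed = 0
        attempts = 0
        while placed < decoys_per_viewpoint and attempts < 200:
            attempts += 1
            pos = int(rng.integers(10_000, max(L - 10_000, 10_001)))
            if any(a <= pos < b for a, b in forbidden.get(vp.chrom, [])):
                continue
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((f"G{gid:04d}", vp.chrom, pos, strand, False, vp.snp_id))
            forbidden[vp.chrom].append((pos - 10_000, pos + 10_000))
            placed += 1
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "tss", "strand", "is_target", "near_snp"]
    )

    # locus activity and H3K27ac peaks per cell type
    peaks: dict[str, pd.DataFrame] = {}
    n_active = int(round(activity_fraction * len(viewpoints)))
    for ct in cell_types:
        order = rng.permutation(len(viewpoints))
        active = {viewpoints[i].snp_id for i in order[:n_active]}
        truth.active[ct] = active
        rows = [
            (vp.chrom, max(0, vp.position - 500), vp.position + 500, f"{ct}_peak_{vp.snp_id}")
            for vp in viewpoints
            if vp.snp_id in active
        ]
        peaks[ct] = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    # CTCF peaks: uniform positions per chromosome
    ctcf_rows = []
    for chrom, L in chrom_lengths.items():
        for pos in np.sort(rng.integers(1000, max(L - 1000, 1001), size=n_ctcf_per_chrom)):
            ctcf_rows.append((chrom, int(pos) - 200, int(pos) + 200, "CTCF"))
    ctcf = pd.DataFrame(ctcf_rows, columns=["chrom", "start", "end", "name"])

    # LD partners: two variants within +/- 50 kbp of each tag SNP
    ld_rows = []
    for vp in viewpoints:
        L = chrom_lengths[vp.chrom]
        for _ in range(2):
            off = int(rng.integers(5_000, 50_000)) * (1 if rng.random() < 0.5 else -1)
            ld_rows.append((vp.snp_id, vp.chrom, int(np.clip(vp.position + off, 0, L - 1))))
    ld = pd.DataFrame(ld_rows, columns=["tag_snp", "variant_chrom", "variant_pos"])

    # expression per cell type, spanning the log2(RPKM) = -0.5 boundary
    expression: dict[str, pd.DataFrame] = {}
    target_ids = genes.loc[genes["is_target"], "gene_id"].tolist()
    n_expr_targets = int(round(expressed_target_fraction * len(target_ids)))
    for ct in cell_types:
        expressed: set[str] = set(target_ids[:n_expr_targets])
        values = {}
        for g in target_ids:
            values[g] = (
                2.0 + rng.normal(0, 0.3) if g in expressed else -2.0 + rng.normal(0, 0.3)
            )
        decoy_ids = genes.loc[~genes["is_target"], "gene_id"].tolist()
        for i, g in enumerate(decoy_ids):
            if i % 2 == 0:
                values[g] = 1.0 + rng.normal(0, 0.3)
                expressed.add(g)
            else:
                values[g] = -2.0 + rng.normal(0, 0.3)
        truth.expressed[ct] = expressed
        expression[ct] = pd.DataFrame(
            sorted(values.items()), columns=["gene_id", "log2_rpkm"]
        )

    # eQTL genes are drawn from the true targets of each SNP
    eqtl_rows = []
    for vp in viewpoints:
        tg = truth.targets.get(vp.snp_id, [])
        for g in tg[: int(round(eqtl_fraction * len(tg)))]:
            eqtl_rows.append((vp.snp_id, g))
    eqtl = pd.DataFrame(eqtl_rows, columns=["snp", "gene_id"])

    # ranked differential-expression table: targets get elevated fold changes
    metric = {
        g: (rng.normal(2.5, 0.5) if t else rng.normal(0.0, 1.0))
        for g, t in zip(genes["gene_id"], genes["is_target"])
    }
    ranked = (
        pd.DataFrame(metric.items(), columns=["gene_id", "metric"])
        .sort_values("metric", ascending=False, kind="stable")
        .reset_index(drop=True)
    )

    known = set(sorted(target_ids)[: int(round(known_fraction * len(target_ids)))])
    return {
        "genes": genes,
        "peaks": peaks,
        "ctcf": ctcf,
        "ld": ld,
        "expression": expression,
        "eqtl": eqtl,
        "ranked_de": ranked,
        "known_genes": known,
    }


def simulate_study(
    config: SimConfig,
    contact_distance: int = 250_000,
    contact_span: int = 30_000,
    contact_coverage: float = 0.9,
    **annotation_kwargs,
) -> Study:
    """Generate a full synthetic study: genome, fragend library, viewpoints
    with planted contacts, coverage profiles for every viewpoint x cell
    type, and all annotation tables, with ground truth attached.

    Viewpoints are spread round-robin over the chromosomes; if the config
    lists no planted contacts, one contact of ``contact_span`` bp at
    ``contact_distance`` bp from each viewpoint is planted (clamped inside
    the chromosome), with coverage probability ``contact_coverage``.
    """
    genome = generate_genome(config)
    library = build_fragend_library(genome)
    chrom_names = list(genome)
    lengths = library.chrom_lengths
    rng = _substream(config.seed, "viewpoints")

    viewpoints: list[ViewpointSpec] = []
    primers: set[str] = set()
    per_chrom = {c: 0 for c in chrom_names}
    counts = [
        config.n_viewpoints // len(chrom_names)
        + (1 if i < config.n_viewpoints % len(chrom_names) else 0)
        for i in range(len(chrom_names))
    ]
    cell_types = [f"ct{i + 1}" for i in range(config.n_cell_types)]
    vi = 0
    for chrom, n_on_chrom in zip(chrom_names, counts):
        L = lengths[chrom]
        lo, hi = int(0.15 * L), int(0.85 * L)
        for j in range(n_on_chrom):
            vi += 1
            pos = lo + (hi - lo) * (2 * j + 1) // (2 * n_on_chrom)
            primer = _random_primer(rng)
            while primer in primers or any(
                primer.startswith(p) or p.startswith(primer) for p in primers
            ):
                primer = _random_primer(rng)
            primers.add(primer)
            viewpoints.append(
                ViewpointSpec(
                    snp_id=f"rs{vi:04d}",
                    chrom=chrom,
                    position=pos,
                    primer=primer,
                    cell_types=tuple(cell_types),
                )
            )
            per_chrom[chrom] += 1

    truth = GroundTruth()
    for vp in viewpoints:
        L = lengths[vp.chrom]
        if config.planted_contacts:
            truth.planted[vp.snp_id] = [
                c for c in config.planted_contacts if c.chrom == vp.chrom
            ]
            continue
        side = 1 if vp.position + contact_distance + contact_span < L - 10_000 else -1
        start = vp.position + side * contact_distance - (contact_span if side < 0 else 0)
        start = int(np.clip(start, 10_000, L - contact_span - 10_000))
        truth.planted[vp.snp_id] = [
            PlantedContact(vp.chrom, start, start + contact_span, contact_coverage)
        ]

    profiles: dict[tuple[str, str], CoverageProfile] = {}
    for vp in viewpoints:
        for ct in cell_types:
            profile, _ = simulate_coverage(
                library, vp, config, cell_type=ct, planted=truth.planted[vp.snp_id]
            )
            profiles[(vp.snp_id, ct)] = profile

    ann = generate_annotations(
        config, truth, viewpoints, cell_types, lengths, **annotation_kwargs
    )
    return Study(
        config=config,
        genome=genome,
        library=library,
        viewpoints=viewpoints,
        cell_types=cell_types,
        profiles=profiles,
        truth=truth,
        genes=ann["genes"],
        peaks=ann["peaks"],
        ctcf=ann["ctcf"],
        ld=ann["ld"],
        expression=ann["expression"],
        eqtl=ann["eqtl"],
        ranked_de=ann["ranked_de"],
        known_genes=ann["known_genes"],
    )
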