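"""Synthetic DGE-tag experiments with complete ground truth.

Emulates the statistical structure of a two-species, three-stage,
two-replicate tag-sequencing experiment: a random reference
transcriptome (every transcript guaranteed at least one CATG + 17 nt tag
site), a second species derived by point substitutions at a configured
divergence rate (the analysis maps both species against species-1
references, as cross-species tag studies do), skewed gene abundances,
planted species- and stage-effect fold changes, replicate-level
dispersion, tag-site usage biased toward the 3'-most CATG site (the
protocol captures bead-bound 3' cDNA fragments), contaminant reads
exercising the genome-fallback and unknown-tag paths, per-base
sequencing error, and a trickle of adaptor-only reads.

Every emitted read's origin is recorded, so downstream QC, mapping and
DE calls can be checked against the generator's bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import Design, STAGES
from .tag_reference import ANCHOR, TAG_LENGTH, extract_tags

#: 28 nt of 3' adaptor so that tag (21) + adaptor = the platform's 49 bp read
DEFAULT_ADAPTOR = "TCGTATGCCGTCTTCTGCTTGAAAAAAA"
READ_LENGTH = 49
_BASES = np.array(list("ACGT"))

# per-read source codes in the ground truth (non-negative = gene index)
SOURCE_GENOME = -1
SOURCE_UNKNOWN = -2
SOURCE_ADAPTOR = -3


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment; the seed is mandatory.

    Defaults describe the reference study conditions: 2,000 genes, 12
    libraries of 100,000 tags (2 species x 3 stages x 2 replicates), 10%
    of genes with a planted |log2FC| = 3 species effect, 10% with a
    declining stage profile, log-normal baseline abundances, and modest
    replicate dispersion.
    """

    seed: int
    n_genes: int = 2000
    length_range: tuple[int, int] = (400, 1500)
    depth: int = 100_000
    n_species: int = 2
    species_names: tuple[str, str] = ("Amel", "Acer")
    stages: tuple[str, ...] = STAGES
    replicates: int = 2
    # baseline abundance law (natural-log parameters)
    abundance_mu: float = 1.0
    abundance_sigma: float = 1.5
    # planted effects
    species_effect_fraction: float = 0.1
    species_effect_log2: float = 3.0
    stage_effect_fraction: float = 0.1
    stage_effect_log2: float = 1.5  # per-step decline from newly-emerged to forager
    de_min_abundance_quantile: float = 0.5
    # nuisance structure
    replicate_sigma: float = 0.2  # natural-log SD of per-library gene noise
    error_rate: float = 0.001  # per base
    n_rate: float = 0.0005  # per base, uncalled positions
    adaptor_only_rate: float = 0.001  # per read, empty-insert ligations
    genome_background_fraction: float = 0.03  # reads from unannotated genomic CATG sites
    unknown_fraction: float = 0.05  # reads from tags >=2 mismatches from any reference tag
    divergence: float = 0.01  # per-base substitution rate between the species
    intergenic_length: int = 300
    site_decay: float = 0.7  # geometric weight per site upstream of the 3'-most
    workers_per_library: int = 60
    adaptor: str = DEFAULT_ADAPTOR

    def __post_init__(self) -> None:
        for name in (
            "species_effect_fraction",
            "stage_effect_fraction",
            "de_min_abundance_quantile",
            "error_rate",
            "n_rate",
            "adaptor_only_rate",
            "genome_background_fraction",
            "unknown_fraction",
            "divergence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def n_libraries(self) -> int:
        return self.n_species * len(self.stages) * self.replicates


@dataclass
class Reference:
    """Both species' transcript sets plus the species-1 genome."""

    transcripts: dict[str, dict[str, str]]  # species -> gene -> sequence
    genome: dict[str, str]  # chromosome id -> sequence
    intergenic_tags: list[str]  # genomic CATG tags outside any transcript

    def write_fastas(self, out_dir: Path, species_names) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for sp in species_names:
            p = out_dir / f"transcripts_{sp}.fasta"
            with open(p, "w") as fh:
                for gene, seq in self.transcripts[sp].items():
                    fh.write(f">{gene}\n{seq}\n")
            paths[f"transcripts_{sp}"] = p
        p = out_dir / "genome.fasta"
        with open(p, "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n{seq}\n")
        paths["genome"] = p
        return paths


@dataclass
class GroundTruth:
    """Generator bookkeeping covering every emitted read."""

    config: SimulationConfig
    de_table: pd.DataFrame  # per gene: baseline, species_de, direction, stage_de
    true_counts: pd.DataFrame  # genes x libraries reads emitted per gene
    pools: pd.DataFrame  # per library: gene/genome/unknown/adaptor read masses
    read_sources: dict[str, np.ndarray] = field(default_factory=dict)
    read_errors: dict[str, np.ndarray] = field(default_factory=dict)

    def species_de_genes(self) -> set[str]:
        return set(self.de_table.index[self.de_table["species_de"]])

    def write_tsvs(self, out_dir: Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.de_table.to_csv(out_dir / "truth_de.tsv", sep="\t")
        self.true_counts.to_csv(out_dir / "truth_counts.tsv", sep="\t")
        self.pools.to_csv(out_dir / "truth_pools.tsv", sep="\t")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Point-substitute each base independently with probability ``rate``."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def simulate_reference(config: SimulationConfig) -> Reference:
    """Random transcriptomes for both species and a species-1 genome.

    Species-2 transcripts derive from species-1 by point substitutions at
    the configured divergence; with divergence 0 the two are identical.
    The genome embeds the species-1 transcripts in random intergenic
    sequence, whose own CATG sites feed the genome-background read pool.
    """
    ss = np.random.SeedSequence([config.seed, 0])
    rng = np.random.default_rng(ss)
    sp1, sp2 = config.species_names
    t1: dict[str, str] = {}
    lo, hi = config.length_range
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        gene = f"gene{i:0{width}d}"
        length = int(rng.integers(lo, hi + 1))
        seq = _random_dna(rng, length)
        if not extract_tags(seq):
            pos = length - TAG_LENGTH
            seq = seq[:pos] + ANCHOR + seq[pos + 4 :]
        t1[gene] = seq
    t2 = {g: _mutate(rng, s, config.divergence) for g, s in t1.items()}

    pieces = []
    intergenic: list[str] = []
    for gene, seq in t1.items():
        spacer = _random_dna(rng, config.intergenic_length)
        intergenic.extend(tag for _, tag in extract_tags(spacer))
        pieces.append(spacer)
        pieces.append(seq)
    tail = _random_dna(rng, config.intergenic_length)
    intergenic.extend(tag for _, tag in extract_tags(tail))
    pieces.append(tail)
    genome = {"chr1": "".join(pieces)}
    return Reference(
        transcripts={sp1: t1, sp2: t2}, genome=genome, intergenic_tags=intergenic
    )


def _unknown_tag_pool(
    rng: np.random.Generator, forbidden: set[str], n_pool: int = 100
) -> list[str]:
    """Random CATG tags at Hamming distance >= 2 from every reference tag."""

    def far_enough(tag: str) -> bool:
        if tag in forbidden:
            return False
        for i in range(4, TAG_LENGTH):
            for b in "ACGT":
                if b != tag[i] and tag[:i] + b + tag[i + 1 :] in forbidden:
                    return False
        return True

    pool: list[str] = []
    while len(pool) < n_pool:
        tag = ANCHOR + _random_dna(rng, TAG_LENGTH - 4)
        if far_enough(tag):
            pool.append(tag)
    return pool


def _plant_effects(
    config: SimulationConfig, rng: np.random.Generator, baseline: np.ndarray
) -> pd.DataFrame:
    """Choose disjoint species- and stage-effect gene sets among genes at or
    above the configured baseline-abundance quantile (planted fold changes
    below the detection floor would be unmeasurable at any threshold)."""
    n = config.n_genes
    floor = np.quantile(baseline, config.de_min_abundance_quantile)
    eligible = np.flatnonzero(baseline >= floor)
    n_sp = round(config.species_effect_fraction * n)
    n_st = round(config.stage_effect_fraction * n)
    picked = rng.choice(eligible, size=min(n_sp + n_st, len(eligible)), replace=False)
    sp_idx = picked[:n_sp]
    st_idx = picked[n_sp:]
    species_de = np.zeros(n, dtype=bool)
    species_de[sp_idx] = True
    direction = np.full(n, "", dtype=object)
    direction[sp_idx[::2]] = "up_in_species1"
    direction[sp_idx[1::2]] = "up_in_species2"
    stage_de = np.zeros(n, dtype=bool)
    stage_de[st_idx] = True
    width = len(str(n))
    return pd.DataFrame(
        {
            "baseline": baseline,
            "species_de": species_de,
            "species_direction": direction,
            "stage_de": stage_de,
        },
        index=[f"gene{i:0{width}d}" for i in range(n)],
    )


def simulate_libraries(
    config: SimulationConfig,
    reference: Reference,
    out_dir: Path,
) -> tuple[Design, GroundTruth]:
    """Draw all 12 libraries as 49 bp FASTQ files plus ground truth.

    Per library the expected gene weight is baseline x stage effect x
    species effect x exp(N(0, replicate_sigma)); reads are multinomial
    over genes, then over each gene's tag sites with geometric weights
    from the 3'-most site.  Contaminant reads come from intergenic CATG
    sites and from an unknown-tag pool; errors and N bases are applied at
    the configured per-base rates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sp1, sp2 = config.species_names
    genes = list(reference.transcripts[sp1])
    n = len(genes)

    ss = np.random.SeedSequence([config.seed, 1])
    eff_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    baseline = eff_rng.lognormal(config.abundance_mu, config.abundance_sigma, size=n)
    de_table = _plant_effects(config, eff_rng, baseline)

    # per-species per-gene tag-site lists and geometric usage weights
    site_tags: dict[str, list[list[str]]] = {}
    site_weights: dict[str, list[np.ndarray]] = {}
    for sp in (sp1, sp2):
        tags_sp, weights_sp = [], []
        for g in genes:
            tags = [t for _, t in extract_tags(reference.transcripts[sp][g])]
            k = len(tags)
            w = config.site_decay ** np.arange(k - 1, -1, -1) if k else np.array([])
            tags_sp.append(tags)
            weights_sp.append(w / w.sum() if k else w)
        site_tags[sp] = tags_sp
        site_weights[sp] = weights_sp

    sp_mult = {sp1: np.ones(n), sp2: np.ones(n)}
    up1 = (de_table["species_direction"] == "up_in_species1").to_numpy()
    up2 = (de_table["species_direction"] == "up_in_species2").to_numpy()
    sp_mult[sp2] = np.where(
        up1, 2.0 ** -config.species_effect_log2,
        np.where(up2, 2.0 ** config.species_effect_log2, 1.0),
    )
    stage_mult = {
        stage: np.where(
            de_table["stage_de"].to_numpy(),
            2.0 ** (config.stage_effect_log2 * (1 - k)),
            1.0,
        )
        for k, stage in enumerate(config.stages)
    }

    forbidden: set[str] = set()
    for sp in (sp1, sp2):
        for tags in site_tags[sp]:
            forbidden.update(tags)
    forbidden.update(tag for _, tag in extract_tags(reference.genome["chr1"]))
    unknown_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    unknown_pool = _unknown_tag_pool(unknown_rng, forbidden)
    genome_pool = reference.intergenic_tags or unknown_pool

    rows = []
    lib_seeds = ss.spawn(config.n_libraries)
    true_counts: dict[str, np.ndarray] = {}
    pools_rows = []
    read_sources: dict[str, np.ndarray] = {}
    read_errors: dict[str, np.ndarray] = {}
    lib_index = 0
    for sp in (sp1, sp2):
        for stage in config.stages:
            for rep in range(1, config.replicates + 1):
                lib_id = f"{sp}_{stage}_{rep}"
                rng = np.random.default_rng(lib_seeds[lib_index])
                lib_index += 1
                path = out_dir / f"{lib_id}.fastq"
                counts, pools, sources, errors = _draw_library(
                    config, rng, lib_id, path, genes,
                    baseline * sp_mult[sp] * stage_mult[stage],
                    site_tags[sp], site_weights[sp], genome_pool, unknown_pool,
                )
                rows.append(
                    {
                        "library_id": lib_id,
                        "species": sp,
                        "stage": stage,
                        "replicate": rep,
                        "path": str(path),
                    }
                )
                true_counts[lib_id] = counts
                pools_rows.append({"library_id": lib_id, **pools})
                read_sources[lib_id] = sources
                read_errors[lib_id] = errors

    design = Design(pd.DataFrame(rows), workers_per_library=config.workers_per_library)
    truth = GroundTruth(
        config=config,
        de_table=de_table,
        true_counts=pd.DataFrame(true_counts, index=genes),
        pools=pd.DataFrame(pools_rows).set_index("library_id"),
        read_sources=read_sources,
        read_errors=read_errors,
    )
    return design, truth


def _draw_library(
    config: SimulationConfig,
    rng: np.random.Generator,
    lib_id: str,
    path: Path,
    genes: list[str],
    expected: np.ndarray,
    site_tags: list[list[str]],
    site_weights: list[np.ndarray],
    genome_pool: list[str],
    unknown_pool: list[str],
):
    n = len(genes)
    depth = config.depth
    noise = rng.lognormal(0.0, config.replicate_sigma, size=n)
    w = expected * noise
    w[[len(t) == 0 for t in site_tags]] = 0.0  # site-less genes emit no tags
    p = w / w.sum()

    n_adaptor = rng.binomial(depth, config.adaptor_only_rate)
    n_unknown = rng.binomial(depth, config.unknown_fraction)
    n_genome = rng.binomial(depth, config.genome_background_fraction)
    n_gene = depth - n_adaptor - n_unknown - n_genome
    gene_counts = rng.multinomial(n_gene, p)

    tags: list[str] = []
    sources: list[int] = []
    for gi in np.flatnonzero(gene_counts):
        per_site = rng.multinomial(gene_counts[gi], site_weights[gi])
        for si in np.flatnonzero(per_site):
            tags.extend([site_tags[gi][si]] * per_site[si])
        sources.extend([gi] * gene_counts[gi])
    for pool, code, count in (
        (genome_pool, SOURCE_GENOME, n_genome),
        (unknown_pool, SOURCE_UNKNOWN, n_unknown),
    ):
        idx = rng.integers(len(pool), size=count)
        tags.extend(pool[i] for i in idx)
        sources.extend([code] * count)
    adaptor_read = (config.adaptor * 3)[:READ_LENGTH]
    reads = [t + config.adaptor for t in tags]
    reads.extend([adaptor_read] * n_adaptor)
    sources.extend([SOURCE_ADAPTOR] * n_adaptor)
    src = np.array(sources, dtype=np.int32)
    errors = np.zeros(len(reads), dtype=np.int16)

    # sparse per-base substitution errors and uncalled (N) bases
    quals: dict[int, list[str]] = {}
    base_qual = "I" * READ_LENGTH
    n_err = rng.binomial(len(reads) * READ_LENGTH, config.error_rate)
    for _ in range(n_err):
        ri = int(rng.integers(len(reads)))
        bi = int(rng.integers(READ_LENGTH))
        old = reads[ri][bi]
        if old not in "ACGT":
            continue
        new = "ACGT".replace(old, "")[rng.integers(3)]
        reads[ri] = reads[ri][:bi] + new + reads[ri][bi + 1 :]
        errors[ri] += 1
    n_unc = rng.binomial(len(reads) * READ_LENGTH, config.n_rate)
    for _ in range(n_unc):
        ri = int(rng.integers(len(reads)))
        bi = int(rng.integers(READ_LENGTH))
        reads[ri] = reads[ri][:bi] + "N" + reads[ri][bi + 1 :]
        q = quals.get(ri, list(base_qual))
        q[bi] = "#"
        quals[ri] = q
        errors[ri] += 1

    order = rng.permutation(len(reads))
    with open(path, "w") as fh:
        for out_i, ri in enumerate(order):
            q = "".join(quals[ri]) if ri in quals else base_qual
            fh.write(f"@{lib_id}_{out_i}\n{reads[ri]}\n+\n{q}\n")

    counts = np.zeros(n, dtype=np.int64)
    np.add.at(counts, src[src >= 0], 1)
    pools = {
        "gene_reads": int((src >= 0).sum()),
        "genome_reads": int((src == SOURCE_GENOME).sum()),
        "unknown_reads": int((src == SOURCE_UNKNOWN).sum()),
        "adaptor_reads": int((src == SOURCE_ADAPTOR).sum()),
    }
    return counts, pools, src[order], errors[order]


def simulate_annotation(
    config: SimulationConfig,
    truth: GroundTruth,
    path: Path,
    n_terms: int = 25,
) -> Path:
    """Random gene->term annotation with one term enriched in the planted
    species-effect genes (a positive control for the enrichment stage)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    genes = list(truth.de_table.index)
    species_de = truth.de_table["species_de"].to_numpy()
    terms = [f"TERM{i:03d}" for i in range(n_terms)]
    rows = []
    for gi, gene in enumerate(genes):
        for t in rng.choice(terms, size=int(rng.integers(1, 4)), replace=False):
            rows.append((gene, t, f"synthetic process {t[-3:]}", "biological_process"))
        p_special = 0.6 if species_de[gi] else 0.02
        if rng.random() < p_special:
            rows.append((gene, "TERM_RJ", "royal jelly secretion", "biological_process"))
    path = Path(path)
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(r) + "\n")
    return path


def simulate_experiment(
    config: SimulationConfig, out_dir: Path
) -> tuple[Design, GroundTruth, dict[str, Path]]:
    """One-call fixture generation: reference FASTAs, 12 FASTQ libraries,
    design table, annotation table, truth TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reference = simulate_reference(config)
    paths = reference.write_fastas(out_dir, config.species_names)
    design, truth = simulate_libraries(config, reference, out_dir / "libraries")
    design_path = out_dir / "design.tsv"
    portable = design.table.copy()
    portable["path"] = [
        str(Path(p).relative_to(out_dir)) for p in portable["path"]
    ]
    portable.to_csv(design_path, sep="\t", index=False)
    paths["design"] = design_path
    paths["annotation"] = simulate_annotation(config, truth, out_dir / "annotation.tsv")
    truth.write_tsvs(out_dir / "truth")
    return design, truth, paths
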