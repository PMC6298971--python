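"""Seeded synthetic genomes and metaproteomes with planted ground truth.

The generator emulates the statistical structure the analysis assumes,
at desk scale:

* genomes are runs of decoy genes interleaved with PULs planted from
  architecture templates (susCD tandems plus substrate-diagnostic
  CAZyme/sulfatase genes);
* domain evidence follows the two-of-three consensus pattern for
  planted families, plus optional single-source decoy hits that a
  correct consensus annotator must reject;
* SusC/D protein sequences of one substrate descend from a common
  ancestor (i.i.d. per-site substitution), so different substrates form
  distinct sequence families and trees recover substrate clusters;
* metaproteome count tables carry background proteins plus planted
  SusC/D homologs with substrate-specific temporal peaks over a rising-
  then-falling chlorophyll series.

All randomness derives from one master seed through documented
sub-streams (one per artifact), so identical configurations produce
byte-identical outputs and adding an artifact never perturbs others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    AMINO_ACIDS,
    COMPLETE,
    DomainEvidence,
    GeneRecord,
    Genome,
    NO_SUSCD,
    NO_SUSD,
    PULTemplate,
    TBDT_ONLY,
)
from . import genome_io

# ---------------------------------------------------------------------------
# PUL architecture templates (one per substrate signature, plus
# incomplete-subtype variants)
# ---------------------------------------------------------------------------

_TEMPLATES = [
    PULTemplate("laminarin_A", ("susC", "susD", "GH16", "GH3", "GH16"), "laminarin", "laminarin_A"),
    PULTemplate("laminarin_B", ("susC", "susD", "GH30", "GH17", "GH17", "GH16"), "laminarin", "laminarin_B"),
    PULTemplate("laminarin_CD", ("susC", "susD", "GH16", "GH30", "GH5"), "laminarin", "laminarin_C_or_D"),
    PULTemplate(
        "alpha14_glucan_branched",
        ("susC", "susD", "susE", "GH13", "GH65", "GH31"),
        "alpha14_glucan",
        "alpha14_glucan_branched",
    ),
    PULTemplate(
        "alpha14_glucan_simple", ("susC", "susD", "GH13", "GH65"), "alpha14_glucan", "alpha14_glucan_simple"
    ),
    PULTemplate("alginate", ("susC", "susD", "PL6", "PL7", "PL17"), "alginate", "alginate"),
    PULTemplate(
        "alginate_no_susCD", ("PL6", "PL7", "PL17"), "alginate", "alginate", NO_SUSCD
    ),
    PULTemplate(
        "alpha_mannan_sulfated",
        ("susC", "susD", "GH92", "GH92", "GH92", "sulfatase", "sulfatase", "GH2", "GH88"),
        "alpha_mannan_sulfated",
        "alpha_mannan_sulfated",
    ),
    PULTemplate(
        "alpha_mannan_plain",
        ("susC", "susD", "GH76", "GH125", "GH38"),
        "alpha_mannan",
        "alpha_mannan_plain",
    ),
    PULTemplate("beta_mannan", ("susC", "susD", "GH130", "GH26"), "beta_mannan", "beta_mannan"),
    PULTemplate(
        "fcsp", ("susC", "susD", "GH29", "GH95", "sulfatase", "sulfatase"), "fcsp", "fcsp"
    ),
    PULTemplate(
        "xylan_glucurono", ("susC", "susD", "GH10", "GH43", "GH115"), "xylan", "xylan_glucurono"
    ),
    PULTemplate(
        "xylan_arabino", ("susC", "susD", "GH10", "GH51", "GH43"), "xylan", "xylan_arabino"
    ),
    PULTemplate(
        "xylan_sulfated", ("susC", "susD", "GH10", "GH43", "sulfatase"), "xylan_sulfated", "xylan_sulfated"
    ),
    PULTemplate("xylan_no_susD", ("susC", "GH10", "GH43"), "xylan", "xylan", NO_SUSD),
    PULTemplate(
        "tbdt_glucan", ("tbdt", "GH13", "GH65"), "alpha14_glucan", "alpha14_glucan_simple", TBDT_ONLY
    ),
]


def template_registry() -> dict[str, PULTemplate]:
    """All built-in PUL architecture templates, keyed by name."""
    return {t.name: t for t in _TEMPLATES}


DEFAULT_SUBSTRATE_MIX = {
    "laminarin_A": 2,
    "laminarin_B": 1,
    "alpha14_glucan_branched": 1,
    "alginate": 1,
    "alpha_mannan_sulfated": 1,
    "beta_mannan": 1,
    "xylan_sulfated": 1,
}  # 8 planted PULs per genome, close to the ~7.5 average the pipeline targets

DEFAULT_PEAK_SAMPLES = {
    "laminarin": 4,
    "alpha14_glucan": 6,
    "beta_mannan": 8,
    "xylan_sulfated": 10,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic-data generator (seeded, reproducible)."""

    seed: int = 0
    n_genomes: int = 5
    substrate_mix: dict = field(default_factory=lambda: dict(DEFAULT_SUBSTRATE_MIX))
    mean_decoy_run: float = 4.0  # extra decoy genes beyond the hard separation
    min_separation: int = 5  # decoy genes between PULs; keep > detection gap tolerance
    evidence_noise: float = 0.05  # P(single-source spurious CAZyme hit) per decoy gene
    peptidase_rate: float = 0.1  # P(MEROPS hit) per decoy gene
    within_substrate_p: float = 0.12  # per-site substitution within a SusC/D family
    between_substrate_p: float = 0.7  # divergence of family ancestors from a root
    ancestor_length: int = 300
    # metaproteome block
    n_samples: int = 14
    replicates: int = 2
    n_background: int = 300
    background_lam: float = 30.0
    baseline_lam: float = 1.0
    peak_count: float = 20.0
    count_noise: float = 1.0  # 0 -> counts equal their configured means exactly
    query_divergence_p: float = 0.15
    peak_samples: dict = field(default_factory=lambda: dict(DEFAULT_PEAK_SAMPLES))


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    genomes: list[Genome]
    evidence: dict[str, list[DomainEvidence]]
    truth_puls: pd.DataFrame
    ancestors: dict[str, dict[str, str]]  # substrate -> {'susC': seq, 'susD': seq}
    counts: pd.DataFrame
    queries: dict[str, dict[str, str]]  # class -> {query_id: seq}
    metadata: pd.DataFrame
    truth_queries: pd.DataFrame


# ---------------------------------------------------------------------------
# Protein-family generator
# ---------------------------------------------------------------------------


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(seq: str, p_subst: float, rng: np.random.Generator) -> str:
    """Per-site i.i.d. substitution with probability ``p_subst``, uniform
    over the 19 alternative residues."""
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < p_subst)
    for i in hits:
        alternatives = AMINO_ACIDS.replace(out[i], "")
        out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def generate_protein_family(
    ancestor_length: int, n: int, p_subst: float, seed: int
) -> list[str]:
    """``n`` sequences mutated i.i.d. from one random ancestor.

    Expected pairwise identity between members is approximately
    100 x ((1-p)^2 + p^2/19): a site matches when neither copy mutated,
    or when both coincidentally substituted to the same residue.
    """
    rng = np.random.default_rng(seed)
    ancestor = _random_protein(ancestor_length, rng)
    return [_mutate(ancestor, p_subst, rng) for _ in range(n)]


def expected_family_identity(p: float) -> float:
    """Closed-form expected pairwise identity of ``generate_protein_family``."""
    match = (1 - p) ** 2 + p**2 / 19
    return 100.0 * match


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


def _substrate_ancestors(cfg: GeneratorConfig, rng: np.random.Generator) -> dict:
    """One susC and one susD ancestor per substrate, all derived from a
    shared root at ``between_substrate_p`` so between-family identity is low."""
    registry = template_registry()
    substrates = sorted({t.substrate for t in registry.values()})
    rootC = _random_protein(cfg.ancestor_length, rng)
    rootD = _random_protein(cfg.ancestor_length, rng)
    return {
        sub: {
            "susC": _mutate(rootC, cfg.between_substrate_p, rng),
            "susD": _mutate(rootD, cfg.between_substrate_p, rng),
        }
        for sub in substrates
    }


_SUSD_MODELS = ("PF12741", "PF12771", "PF14322")
_CAZY_SOURCES = ("pfam", "dbcan", "cazy_blast")
_NOISE_FAMILIES = ("GH13", "GH16", "GH2", "GH3", "PL7", "CE4", "CBM6")


def _slot_evidence(
    gene_id: str, slot: str, rng: np.random.Generator
) -> list[DomainEvidence]:
    """Emit the evidence rows that make a planted slot detectable."""

    def hmm_score() -> float:
        return float(30.0 + 40.0 * rng.random())

    def blast_score() -> float:
        return float(5.0 + 20.0 * rng.random())

    if slot == "susC":
        return [DomainEvidence(gene_id, "tigrfam", "TIGR04056", hmm_score())]
    if slot == "susD":
        model = _SUSD_MODELS[rng.integers(len(_SUSD_MODELS))]
        return [DomainEvidence(gene_id, "pfam", model, hmm_score())]
    if slot == "tbdt":
        return [DomainEvidence(gene_id, "pfam", "PF00593", hmm_score())]
    if slot == "sulfatase":
        sub = f"S1_{rng.integers(1, 30)}"
        return [DomainEvidence(gene_id, "sulfatlas", sub, hmm_score())]
    if slot == "peptidase":
        return [DomainEvidence(gene_id, "merops", f"M{rng.integers(1, 90)}", blast_score())]
    if slot in ("susE", "gene"):
        return []
    # CAZy family slot: a 2-of-3 (sometimes 3-of-3) consensus pattern
    n_sources = 2 + int(rng.random() < 0.3)
    sources = [str(s) for s in rng.choice(_CAZY_SOURCES, size=n_sources, replace=False)]
    rows = []
    for src in sources:
        label = slot
        if src != "cazy_blast" and rng.random() < 0.2:
            label = f"{slot}_{rng.integers(1, 50)}"  # subfamily suffix
        score = blast_score() if src == "cazy_blast" else hmm_score()
        rows.append(DomainEvidence(gene_id, src, label, score))
    return rows


def generate_genome(
    config: GeneratorConfig,
    genome_index: int = 0,
    ancestors: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Genome, list[DomainEvidence], pd.DataFrame]:
    """One synthetic genome with planted PULs, its evidence table and truth.

    Planted PULs are separated by >= ``min_separation`` decoy genes.
    Decoy genes may carry single-source CAZyme noise hits (never enough
    for consensus) and MEROPS peptidase hits.  The truth table lists
    each planted PUL's gene ids, generating template, substrate, the
    rule it should classify to and its completeness class.
    """
    if rng is None:
        streams = _streams(config)
        ancestors = ancestors or _substrate_ancestors(config, streams["families"])
        rng = streams[f"genome{genome_index}"]
    assert ancestors is not None
    registry = template_registry()
    genome_id = f"SYN{genome_index + 1:03d}"
    contig = f"{genome_id}_c1"

    planted = [
        name
        for name, count in sorted(config.substrate_mix.items())
        for _ in range(count)
    ]
    rng.shuffle(planted)

    genes: list[GeneRecord] = []
    evidence: list[DomainEvidence] = []
    truth_rows = []
    pos = 100
    counter = 0

    def add_gene(seq: str, slot: str) -> str:
        nonlocal pos, counter
        counter += 1
        gid = f"{genome_id}_g{counter:04d}"
        start = pos
        end = start + 3 * len(seq)
        pos = end + int(rng.integers(50, 200))
        strand = "+" if rng.random() < 0.8 else "-"
        genes.append(GeneRecord(gid, contig, start, end, strand, seq))
        evidence.extend(_slot_evidence(gid, slot, rng))
        return gid

    def add_decoys(n: int) -> None:
        for _ in range(n):
            seq = _random_protein(int(rng.integers(150, 400)), rng)
            gid = add_gene(seq, "gene")
            if rng.random() < config.evidence_noise:
                fam = _NOISE_FAMILIES[rng.integers(len(_NOISE_FAMILIES))]
                src = _CAZY_SOURCES[rng.integers(len(_CAZY_SOURCES))]
                score = 10.0 if src == "cazy_blast" else 60.0
                evidence.append(DomainEvidence(gid, src, fam, score))
            if rng.random() < config.peptidase_rate:
                evidence.append(
                    DomainEvidence(gid, "merops", f"S{rng.integers(1, 60)}", 8.0)
                )

    def decoy_run_length() -> int:
        return config.min_separation + int(rng.poisson(config.mean_decoy_run))

    add_decoys(decoy_run_length())
    for k, name in enumerate(planted):
        template = registry[name]
        gene_ids = []
        for slot in template.slots:
            if slot in ("susC", "susD"):
                seq = _mutate(ancestors[template.substrate][slot], config.within_substrate_p, rng)
            else:
                seq = _random_protein(int(rng.integers(200, 450)), rng)
            gene_ids.append(add_gene(seq, slot))
        truth_rows.append(
            {
                "genome_id": genome_id,
                "pul_index": k + 1,
                "template": name,
                "substrate": template.substrate,
                "expected_rule": template.expected_rule,
                "expected_completeness": template.expected_completeness,
                "gene_ids": ";".join(gene_ids),
            }
        )
        add_decoys(decoy_run_length())

    size_bp = pos + 1000
    genome = Genome(genome_id=genome_id, genes=genes, size_bp=size_bp)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "genome_id",
            "pul_index",
            "template",
            "substrate",
            "expected_rule",
            "expected_completeness",
            "gene_ids",
        ],
    )
    return genome, evidence, truth


# ---------------------------------------------------------------------------
# Metaproteome generation
# ---------------------------------------------------------------------------


def generate_metaproteome(
    config: GeneratorConfig,
    ancestors: dict,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, dict[str, dict[str, str]], pd.DataFrame, pd.DataFrame]:
    """Spectral-count tables, query FASTA sets, sample metadata and truth.

    For every (substrate, peak sample) in ``config.peak_samples`` one
    susC-like and one susD-like query protein is derived from that
    substrate's reference ancestor at ``query_divergence_p``; its
    expected count is ``baseline_lam`` everywhere except ``peak_count``
    at the peak sample.  Counts are Poisson-distributed around their
    means unless ``count_noise`` is 0, in which case they equal the
    means exactly.  Chlorophyll a rises then falls across the series.
    """
    if rng is None:
        rng = _streams(config)["proteome"]

    samples = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    dates = pd.date_range("2010-03-01", periods=config.n_samples, freq="7D")
    peak_idx = config.n_samples // 2 - 1
    chl = 1.0 + 24.0 * np.exp(-0.5 * ((np.arange(config.n_samples) - peak_idx) / 2.2) ** 2)
    metadata = pd.DataFrame(
        {"sample_id": samples, "date": dates.strftime("%Y-%m-%d"), "chlorophyll_a": np.round(chl, 3)}
    )

    def draw(mean: float) -> float:
        if config.count_noise == 0:
            return float(mean)
        return float(rng.poisson(mean))

    rows = []
    lengths = {}
    for b in range(config.n_background):
        pid = f"B{b + 1:04d}"
        lengths[pid] = int(rng.integers(150, 600))
        for s in samples:
            for r in range(config.replicates):
                rows.append((pid, s, f"r{r + 1}", draw(config.background_lam), lengths[pid]))

    queries: dict[str, dict[str, str]] = {"susC": {}, "susD": {}}
    truth_rows = []
    for substrate in sorted(config.peak_samples):
        peak = int(config.peak_samples[substrate])
        if not 0 <= peak < config.n_samples:
            raise ValueError(f"peak sample index {peak} out of range for {substrate}")
        for cls in ("susC", "susD"):
            qid = f"Q_{substrate}_{cls}"
            seq = _mutate(ancestors[substrate][cls], config.query_divergence_p, rng)
            queries[cls][qid] = seq
            for i, s in enumerate(samples):
                mean = config.peak_count if i == peak else config.baseline_lam
                for r in range(config.replicates):
                    rows.append((qid, s, f"r{r + 1}", draw(mean), len(seq)))
            truth_rows.append(
                {
                    "query_id": qid,
                    "protein_class": f"{cls}_like",
                    "substrate": substrate,
                    "peak_sample": samples[peak],
                }
            )

    counts = pd.DataFrame(
        rows,
        columns=["protein_id", "sample_id", "replicate_id", "spectral_count", "protein_length_aa"],
    )
    truth = pd.DataFrame(
        truth_rows, columns=["query_id", "protein_class", "substrate", "peak_sample"]
    )
    return counts, queries, metadata, truth


# ---------------------------------------------------------------------------
# Dataset assembly and serialization
# ---------------------------------------------------------------------------


def _streams(config: GeneratorConfig) -> dict[str, np.random.Generator]:
    """Named sub-streams of the master seed (fixed spawn order: families,
    genome0..genomeN-1, proteome)."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_genomes + 2)
    streams = {"families": np.random.default_rng(children[0])}
    for i in range(config.n_genomes):
        streams[f"genome{i}"] = np.random.default_rng(children[1 + i])
    streams["proteome"] = np.random.default_rng(children[-1])
    return streams


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Full synthetic study: genomes + evidence + truth + metaproteome."""
    streams = _streams(config)
    ancestors = _substrate_ancestors(config, streams["families"])
    genomes, evidence, truths = [], {}, []
    for i in range(config.n_genomes):
        g, ev, truth = generate_genome(config, i, ancestors, streams[f"genome{i}"])
        genomes.append(g)
        evidence[g.genome_id] = ev
        truths.append(truth)
    truth_puls = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(
            columns=[
                "genome_id",
                "pul_index",
                "template",
                "substrate",
                "expected_rule",
                "expected_completeness",
                "gene_ids",
            ]
        )
    )
    counts, queries, metadata, truth_queries = generate_metaproteome(
        config, ancestors, streams["proteome"]
    )
    return SyntheticDataset(
        config=config,
        genomes=genomes,
        evidence=evidence,
        truth_puls=truth_puls,
        ancestors=ancestors,
        counts=counts,
        queries=queries,
        metadata=metadata,
        truth_queries=truth_queries,
    )


def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Serialize a dataset to the exact formats the readers consume."""
    out = Path(out_dir)
    for genome in ds.genomes:
        gdir = out / "genomes" / genome.genome_id
        gdir.mkdir(parents=True, exist_ok=True)
        genome_io.write_genome_gff(genome, gdir / "genes.gff3")
        genome_io.write_protein_fasta(
            {g.gene_id: g.protein_seq for g in genome.genes}, gdir / "proteins.faa"
        )
        genome_io.write_evidence(ds.evidence[genome.genome_id], gdir / "evidence.tsv")
    ds.truth_puls.to_csv(out / "truth_puls.tsv", sep="\t", index=False)

    pdir = out / "proteome"
    pdir.mkdir(parents=True, exist_ok=True)
    ds.counts.to_csv(pdir / "counts.tsv", sep="\t", index=False)
    for cls in ("susC", "susD"):
        genome_io.write_protein_fasta(ds.queries[cls], pdir / f"queries_{cls}.faa")
    ds.metadata.to_csv(pdir / "samples.tsv", sep="\t", index=False)
    ds.truth_queries.to_csv(pdir / "truth_queries.tsv", sep="\t", index=False)


def small_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A reduced configuration for fast tests (fewer genomes, smaller
    metaproteome background)."""
    base = GeneratorConfig(
        seed=seed,
        n_genomes=2,
        n_background=40,
        background_lam=20.0,
    )
    return replace(base, **overrides)
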