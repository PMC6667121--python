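"""Stage orchestration: simulate -> authenticate -> tissue scoring.

These helpers chain the modules into the per-sample pipelines the CLI and
the reproduction script run: de-duplication, class mapping, composition
and junction statistics, damage profiling, and coverage-based tissue
scoring.
"""

from __future__ import annotations

import importlib.resources
import json
import os
from typing import Mapping, Sequence

import pandas as pd

from . import align, authenticate, simulate, tissue
from .reference import ReferenceBundle
from .simulate import ReadRecord


def packaged_mapping_summary() -> list[authenticate.MappingCounts]:
    """The packaged canid study mapping-summary fixture (both platforms)."""
    path = importlib.resources.files("paleorna.data") / "canid_mapping_summary.tsv"
    return authenticate.read_mapping_summary(str(path))


def packaged_mapping_summary_frame() -> pd.DataFrame:
    path = importlib.resources.files("paleorna.data") / "canid_mapping_summary.tsv"
    return pd.read_csv(str(path), sep="\t", comment="#")


def score_sample(
    reads: Sequence[ReadRecord],
    ref: ReferenceBundle,
    sample_id: str = "sample",
    *,
    dedup: bool = True,
    min_len: int | None = None,
    seed: int = 0,
    pairing: tissue.AssociationPairing | None = None,
    index: align.KmerIndex | None = None,
) -> tissue.TissueScoreVector:
    """Reads -> mRNA coverage -> cumulative tissue-score vector."""
    if dedup:
        reads = align.deduplicate(reads)
    refs = ref.reference_sequences("mRNA")
    aln = align.map_reads(
        reads, refs, "mRNA", sample_id=sample_id, seed=seed, index=index
    )
    if min_len is not None:
        aln = align.filter_min_length(aln, min_len)
    lengths = {t: len(s) for t, s in refs.items()}
    coverage = align.mean_coverage(aln, lengths)
    if pairing is None:
        pairing = tissue.build_pairing(ref.array_matrix)
    return tissue.tissue_scores(coverage, pairing, sample_id=sample_id)


def authenticate_sample(
    reads: Sequence[ReadRecord],
    ref: ReferenceBundle,
    sample_id: str = "sample",
    *,
    total_reads: int | None = None,
    dedup: bool = True,
    seed: int = 0,
    damage_span: int = 25,
) -> dict:
    """Full authentication battery for one read set.

    Returns a dict with mapping counts, composition metrics, junction
    counts and the transcriptome damage profile.
    """
    total = total_reads if total_reads is not None else len(reads)
    dup_rate = authenticate.duplication_rate(reads) if reads else float("nan")
    # composition tallies use duplicates-retained mappings; junction and
    # damage statistics use the de-duplicated alignments
    class_sets = {}
    for cls in ("genome", "mRNA", "rRNA", "tRNA"):
        refs = ref.reference_sequences(cls)
        class_sets[cls] = align.map_reads(
            reads, refs, cls, sample_id=sample_id, seed=seed
        )
    counts = authenticate.count_mappings(sample_id, total, class_sets)
    L_g = len(ref.genome)
    L_t = sum(len(s) for s in ref.transcripts.values())
    metrics = authenticate.CompositionMetrics(
        sample_id=sample_id,
        endogenous_percent=authenticate.endogenous_percent(counts),
        rrna_proportion=authenticate.rrna_proportion(counts),
        enrichment_factor=authenticate.enrichment_factor(counts, L_g, L_t),
        duplication_rate=dup_rate,
    )
    mrna_aln = (
        align.deduplicate(class_sets["mRNA"]) if dedup else class_sets["mRNA"]
    )
    genome_aln = (
        align.deduplicate(class_sets["genome"]) if dedup else class_sets["genome"]
    )
    jindex = authenticate.build_junction_index(ref.genes)
    junctions = authenticate.count_junction_straddlers(
        mrna_aln, genome_aln, jindex, sample_id=sample_id
    )
    damage = authenticate.damage_profile(
        mrna_aln, ref.reference_sequences("mRNA"),
        span=damage_span, sample_id=sample_id,
    )
    return {
        "counts": counts,
        "metrics": metrics,
        "junctions": junctions,
        "damage": damage,
        "class_sets": class_sets,
    }


def simulate_panel(
    ref: ReferenceBundle,
    tissues: Sequence[str],
    *,
    seed: int = 0,
    n_reads: int = 5000,
) -> dict[str, tuple[list[ReadRecord], simulate.TruthSet]]:
    """One modern control library per tissue, with per-tissue derived seeds."""
    out = {}
    for i, t in enumerate(tissues):
        cfg = simulate.control_config(t, seed=seed * 1009 + i, n_reads=n_reads)
        out[t] = simulate.simulate_sample(ref, cfg)
    return out


def run_simulate(config: Mapping, outdir) -> dict:
    """Generate a full fixture directory from a config mapping.

    Writes reference files, four control tissues, one degraded ('ancient')
    sample, a blank, and per-sample truth tables.  Returns run metadata.
    """
    from .reference import build_reference, write_reference

    seed = int(config.get("seed", 0))
    n_genes = int(config.get("n_genes", 60))
    n_reads = int(config.get("n_reads", 5000))
    tissues = list(config.get("tissues", ["skin", "liver", "muscle", "cartilage"]))
    ancient_tissue = str(config.get("ancient_tissue", tissues[0]))

    ref = build_reference(n_genes, seed=seed)
    for t in tissues:
        if t not in ref.tissues:
            raise ValueError(f"config tissue {t!r} not in reference tissues")
    os.makedirs(outdir, exist_ok=True)
    write_reference(ref, os.path.join(outdir, "reference"))

    meta = {"seed": seed, "n_genes": n_genes, "n_reads": n_reads,
            "tissues": tissues, "ancient_tissue": ancient_tissue,
            "samples": {}}

    for i, t in enumerate(tissues):
        cfg = simulate.control_config(t, seed=seed * 1009 + i, n_reads=n_reads)
        reads, truth = simulate.simulate_sample(ref, cfg)
        simulate.write_fastq(reads, os.path.join(outdir, f"control_{t}.fastq"))
        truth.to_tsv(os.path.join(outdir, f"control_{t}.truth.tsv"))
        meta["samples"][f"control_{t}"] = {"seed": cfg.seed, "role": "control",
                                           "tissue": t}
    acfg = simulate.ancient_config(
        ancient_tissue, seed=seed * 1009 + 500, n_reads=n_reads
    )
    reads, truth = simulate.simulate_sample(ref, acfg)
    simulate.write_fastq(reads, os.path.join(outdir, "ancient.fastq"))
    truth.to_tsv(os.path.join(outdir, "ancient.truth.tsv"))
    meta["samples"]["ancient"] = {"seed": acfg.seed, "role": "ancient",
                                  "tissue": ancient_tissue}

    bcfg = simulate.SimulationConfig(
        seed=seed * 1009 + 900, n_reads=min(n_reads, 2000), tissue=tissues[0]
    )
    breads, btruth = simulate.simulate_blank(bcfg, ref, trace_frac=0.0005)
    simulate.write_fastq(breads, os.path.join(outdir, "blank.fastq"))
    btruth.to_tsv(os.path.join(outdir, "blank.truth.tsv"))
    meta["samples"]["blank"] = {"seed": bcfg.seed, "role": "blank"}

    with open(os.path.join(outdir, "run_metadata.json"), "w") as fh:
        json.dump(meta, fh, indent=2)
    return meta
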