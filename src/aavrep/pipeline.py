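"""End-to-end orchestration: reference -> simulation -> hits -> selection ->
classification -> ITR calls -> ratio tables -> digest predictions.

Every run writes a resolved-config snapshot next to its outputs so results
are reproducible from the bundle alone.  All randomness derives from the
single config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .classify import (Thresholds, category_ratios, classify as classify_path,
                       normalize_per_mito, segments_from_hits)
from . import hits as hl
from . import itr as itrmod
from .digest import Unit, band_table, hh_dimer, ht_concatemer, monomer
from .reference import GenomeSpec, build_genome, write_reference
from .simulate import (
    SimConfig,
    make_decoy_reference,
    simulate_molecules,
    simulate_reads,
    truth_table,
    write_molecules_fasta,
    write_reads_fastq,
)

logger = logging.getLogger("aavrep")

__all__ = ["RunConfig", "run_pipeline", "classify_reads", "standard_band_tables"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run (simulation study conditions plus all
    stage thresholds)."""

    seed: int = 1
    category_counts: dict[int, int] = field(
        default_factory=lambda: {k: 50 for k in range(1, 8)})
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    mito_decoy_count: int = 200
    e_max: float = 0.1
    sum_threshold: float = 3000.0
    orientation_margin: int = 4
    run_itr_stage: bool = True

    def sim_config(self) -> SimConfig:
        return SimConfig(category_counts=dict(self.category_counts),
                         sub_rate=self.sub_rate, ins_rate=self.ins_rate,
                         del_rate=self.del_rate,
                         mito_decoy_count=self.mito_decoy_count,
                         seed=self.seed)


def classify_reads(reads, genome, *, e_max: float = 0.1,
                   sum_threshold: float = 3000.0,
                   thresholds: Thresholds = Thresholds(),
                   mito_reference: str | None = None):
    """Align, select and classify a list of (read_id, sequence) pairs.

    Returns (calls, hitsets, mito_count): category calls for selected
    reads, all per-read hit sets, and the number of reads assigned to the
    decoy reference (better summed hits against it than against the
    genome).
    """
    ref = genome.sequence
    all_hits = []
    mito_count = 0
    for rid, seq in reads:
        ah = hl.builtin_local_hits(rid, seq, ref, subject_id="aav")
        if mito_reference is not None:
            mh = hl.builtin_local_hits(rid, seq, mito_reference,
                                       subject_id="mito")
            if (sum(h.aligned_length for h in mh)
                    > sum(h.aligned_length for h in ah)):
                mito_count += 1
                continue
        all_hits.extend(ah)
    hitsets = hl.filter_and_select(all_hits, e_max=e_max,
                                   sum_threshold=sum_threshold)
    calls = []
    for hs in hitsets:
        if not hs.selected:
            continue
        path = segments_from_hits(hs, thresholds=thresholds)
        calls.append(classify_path(path, genome.total_len,
                                  genome.itr_intervals, thresholds))
    return calls, hitsets, mito_count


def standard_band_tables() -> pd.DataFrame:
    """The published digest predictions as one table: the 4.7-kb genome cut
    at nt 1,882 (monomer, head-to-head, head-to-tail) with a rep probe
    upstream of the cut, and the 2.0/3.8-kb vector genomes cut at nt 815
    with transgene probes downstream of the cut."""
    aav = Unit(4700, "+", (1882,), (900, 1800))
    gfp = Unit(2000, "+", (815,), (900, 1900))
    mch = Unit(3800, "+", (815,), (900, 1900))
    models = {
        "AAV2 monomer / HindIII": monomer(4700, 1882, (900, 1800)),
        "AAV2 HH dimer (proximal junction) / HindIII":
            hh_dimer(aav, join="cut_proximal"),
        "AAV2 HH dimer (distal junction) / HindIII":
            hh_dimer(aav, join="cut_distal"),
        "AAV2 HT trimer / HindIII": ht_concatemer(aav, 3),
        "rAAVGFP monomer / SalI": monomer(2000, 815, (900, 1900)),
        "rAAVmC monomer / SalI": monomer(3800, 815, (900, 1900)),
        "rAAVGFP HT dimer / SalI": ht_concatemer(gfp, 2),
        "rAAVmC HT dimer / SalI": ht_concatemer(mch, 2),
        "rAAVGFP HH dimer / SalI": hh_dimer(gfp),
        "rAAVmC HH dimer / SalI": hh_dimer(mch),
        "mixed HH (GFP+mC) / SalI": hh_dimer(gfp, mch),
    }
    return band_table(models)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage and write the report bundle into ``outdir``.

    Returns a summary dict (also written as ``summary.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    yaml.safe_dump(dataclasses.asdict(config),
                   open(out / "resolved_config.yaml", "w"))

    logger.info("stage=reference building annotated genome")
    genome = build_genome(GenomeSpec(seed=config.seed))
    write_reference(genome, out / "reference.fasta", out / "reference.bed",
                    out / "enzyme_sites.tsv")

    logger.info("stage=simulate generating molecules and reads")
    sim = config.sim_config()
    molecules = simulate_molecules(genome, sim)
    mito_ref = make_decoy_reference(sim.mito_len, seed=sim.seed)
    reads = simulate_reads(molecules, sim, decoy_reference=mito_ref)
    write_molecules_fasta(molecules, out / "molecules.fasta")
    write_reads_fastq(reads, out / "reads.fastq")
    truth = truth_table(reads)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    logger.info("stage=hits aligning %d reads", len(reads))
    calls, hitsets, mito_count = classify_reads(
        [(r.read_id, r.sequence) for r in reads], genome,
        e_max=config.e_max, sum_threshold=config.sum_threshold,
        mito_reference=mito_ref if config.mito_decoy_count else None)

    all_hits = [h for hs in hitsets for h in hs.hits]
    hl.write_blast_tab(all_hits, out / "hits.blast6.tsv")
    pd.DataFrame({
        "read_id": [hs.read_id for hs in hitsets],
        "hit_sum": [hs.hit_sum for hs in hitsets],
        "selected": [hs.selected for hs in hitsets],
    }).to_csv(out / "selection.tsv", sep="\t", index=False)

    logger.info("stage=classify %d selected reads", len(calls))
    calls_df = pd.DataFrame({
        "read_id": [c.read_id for c in calls],
        "category": [c.category for c in calls],
        "category_name": [c.category_name for c in calls],
        "n_full_units": [c.n_full_units for c in calls],
        "junctions": [",".join(c.junction_labels) for c in calls],
        "itr_only": [c.itr_only for c in calls],
        "notes": [c.notes for c in calls],
    })
    calls_df.to_csv(out / "category_calls.tsv", sep="\t", index=False)
    ratios = category_ratios(calls) if calls else pd.DataFrame()
    ratios.to_csv(out / "category_ratios.tsv", sep="\t", index=False)

    if config.run_itr_stage:
        logger.info("stage=itr orientation calls")
        seq_by_id = {r.read_id: r.sequence for r in reads}
        selected_ids = [hs.read_id for hs in hitsets if hs.selected]
        rows = []
        for rid in selected_ids:
            itr_calls, verdict = itrmod.analyze_read_itrs(
                rid, seq_by_id[rid], genome, margin=config.orientation_margin)
            for c in itr_calls:
                rows.append({"read_id": rid, "occurrence": c.occurrence,
                             "q_start": c.q_start, "q_end": c.q_end,
                             "orientation": c.orientation,
                             "score_margin": c.score_margin, "trt": c.trt,
                             "uniformity": verdict})
        pd.DataFrame(rows).to_csv(out / "itr_calls.tsv", sep="\t", index=False)

    logger.info("stage=digest band predictions")
    bands = standard_band_tables()
    bands.to_csv(out / "digest_bands.tsv", sep="\t", index=False)

    # truth-aware confusion matrix
    truth_by_read = dict(zip(truth.read_id, truth.category))
    conf = pd.crosstab(
        pd.Series([truth_by_read[c.read_id] for c in calls], name="truth"),
        pd.Series([c.category for c in calls], name="called"), dropna=False)
    conf.to_csv(out / "confusion_matrix.tsv", sep="\t")
    agree = sum(truth_by_read[c.read_id] == c.category for c in calls)

    summary = {
        "n_molecules": len(molecules),
        "n_reads": len(reads),
        "n_selected": len(calls),
        "n_decoy_assigned": mito_count,
        "truth_agreement": agree / len(calls) if calls else float("nan"),
        "per_10k_mito": {
            str(cat): normalize_per_mito(
                sum(c.category == cat for c in calls), mito_count)
            for cat in range(1, 8)
        } if mito_count else {},
    }
    json.dump(summary, open(out / "summary.json", "w"), indent=2)
    logger.info("stage=done summary=%s", summary)
    return summary
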