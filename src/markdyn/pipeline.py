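"""End-to-end orchestration of the analysis stages on one input bundle.

``run_pipeline`` executes, in order: consensus -> annotate -> quantify ->
diffbind -> correlate -> cooccupancy -> colocalize -> motifs -> tissues.
Inputs default to the synthetic study written by the generator for the
configured seed.  Every stage writes TSV/JSON outputs into the output
directory and the run ends with a provenance manifest (stage list,
record counts, sha256 digests, resolved configuration).  A rerun with
unchanged inputs reproduces every output byte for byte; stages whose
outputs already exist are skipped unless a rerun is forced, and forcing
or regenerating one stage reruns everything downstream of it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .consensus import call_consensus, filter_by_qvalue, merge_conditions
from .diffbind import bin_tmm_factors, count_fragments, differential_binding
from .genes import FeatureClass, assign_features
from .intervals import GenomicInterval
from .integration import (
    build_occupancy_ledger,
    colocalization_fraction,
    cooccupancy_fractions,
    correlate_binding_expression,
    transition_flows,
)
from .motifs import enrich_motifs, extract_sequences, gc_content
from .simulate import SimulationConfig, SyntheticStudy, simulate_study
from .tissues import linkage_newick, similarity, upset_counts, ward_cluster

STAGES = (
    "consensus",
    "annotate",
    "quantify",
    "diffbind",
    "correlate",
    "cooccupancy",
    "colocalize",
    "motifs",
    "tissues",
)


@dataclass
class PipelineConfig:
    """All tunables of the workflow, with the study's stated defaults."""

    outdir: Path
    seed: int = 0
    min_neglog10_q: float = 6.0
    min_support: int = 2
    promoter_window: tuple[int, int] = (-1000, 500)
    enhancer_window: tuple[int, int] = (-10000, -1000)
    bin_size: int = 10_000
    fdr: float = 0.01
    pos_threshold: float = 0.8
    neg_threshold: float = -0.8
    scan_p: float = 1e-4
    motif_fdr: float = 0.05
    cut_k: int = 2
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        self.simulation = SimulationConfig(
            **{**asdict(self.simulation), "seed": self.seed}
        )

    @classmethod
    def from_yaml(cls, path, outdir=None) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        if outdir is not None:
            raw["outdir"] = outdir
        for key in ("promoter_window", "enhancer_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_df(path: Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


class PipelineRun:
    """One execution over a synthetic study bundle."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = config.outdir
        self.study: SyntheticStudy | None = None
        self._consensus: dict | None = None
        self._merged = None
        self._counts = None
        self._diffbind: dict | None = None
        self._annotations = None

    # ----------------------------------------------------------- inputs

    def prepare_inputs(self) -> Path:
        inputs = self.out / "inputs"
        self.study = simulate_study(self.cfg.simulation)
        if (inputs / "genome.fa").exists():
            return inputs
        inputs.mkdir(parents=True, exist_ok=True)
        (inputs / "narrowpeak").mkdir(exist_ok=True)
        (inputs / "fragments").mkdir(exist_ok=True)
        st = self.study
        mio.write_fasta(inputs / "genome.fa", st.genome)
        mio.write_gene_table(inputs / "genes.tsv", st.genes)
        for (mark, tp), reps in st.replicate_peaks.items():
            for r, peaks in enumerate(reps):
                mio.write_narrowpeak(
                    inputs / "narrowpeak" / f"{mark}_{tp}_rep{r + 1}.narrowPeak",
                    peaks,
                )
        for sample, frags in st.fragments().items():
            mio.write_bed6(inputs / "fragments" / f"{sample}.bed", frags)
        mio.write_expression(inputs / "expression.tsv", st.expression)
        mio.write_meme_motifs(inputs / "motifs.meme", st.pwms)
        fp = st.footprints
        mio.write_bed6(
            inputs / "footprints.bed",
            [GenomicInterval(r.chrom, r.start, r.end) for r in fp.itertuples()],
            names=[f"{r.gene_id}:{r.role}" for r in fp.itertuples()],
        )
        st.tissue_occupancy.astype(int).to_csv(
            inputs / "tissue_occupancy.tsv", sep="\t", index_label="gene_id"
        )
        truth_dir = inputs / "truth"
        truth_dir.mkdir(exist_ok=True)
        _write_df(truth_dir / "gene_table.tsv", st.truth.gene_table)
        _write_df(truth_dir / "peak_table.tsv", st.truth.peak_table)
        self.cfg.simulation.to_yaml(inputs / "simulation.yaml")
        return inputs

    # ----------------------------------------------------------- stages

    def stage_consensus(self, stage_dir: Path) -> dict:
        st = self.study
        counts = {}
        self._consensus = {}
        inputs = self.out / "inputs" / "narrowpeak"
        for (mark, tp), reps in st.replicate_peaks.items():
            rep_sets = [
                filter_by_qvalue(
                    mio.read_narrowpeak(
                        inputs / f"{mark}_{tp}_rep{r + 1}.narrowPeak"
                    ),
                    self.cfg.min_neglog10_q,
                )
                for r in range(len(reps))
            ]
            cs = call_consensus(rep_sets, self.cfg.min_support, condition=tp)
            self._consensus[(mark, tp)] = cs
            counts[f"{mark}:{tp}"] = len(cs)
            rows = [
                {
                    "chrom": p.interval.chrom,
                    "start": p.interval.start,
                    "end": p.interval.end,
                    "name": f"{mark}_{tp}_c{i + 1}",
                    "support": p.support_count,
                    "condition": tp,
                }
                for i, p in enumerate(cs.peaks)
            ]
            _write_df(stage_dir / f"{mark}_{tp}.consensus.tsv", pd.DataFrame(rows))
        _write_json(stage_dir / "summary.json", {"peak_counts": counts})
        return {"consensus_sets": len(self._consensus)}

    def stage_annotate(self, stage_dir: Path) -> dict:
        anchor = self.cfg.simulation.marks[0]
        genes = self.study.genes
        summary = {}
        for tp in self.cfg.simulation.timepoints:
            ivs = self._consensus[(anchor, tp)].intervals
            assigns = assign_features(
                ivs, genes, self.cfg.promoter_window, self.cfg.enhancer_window
            )
            rows = [
                {
                    "chrom": a.peak.chrom,
                    "start": a.peak.start,
                    "end": a.peak.end,
                    "feature_class": a.feature_class.value,
                    "gene_id": a.gene_id or ".",
                    "tss_distance": a.tss_distance if a.tss_distance is not None else "",
                }
                for a in assigns
            ]
            _write_df(stage_dir / f"{anchor}_{tp}.annotation.tsv", pd.DataFrame(rows))
            genes_with_peak = {a.gene_id for a in assigns if a.gene_id}
            promoter_genes = {
                a.gene_id
                for a in assigns
                if a.feature_class is FeatureClass.PROMOTER
            }
            summary[tp] = {
                "n_peaks": len(ivs),
                "genes_with_peak": len(genes_with_peak),
                "genes_with_promoter_peak": len(promoter_genes),
            }
        _write_json(stage_dir / "summary.json", summary)
        return {"timepoints": len(summary)}

    def stage_quantify(self, stage_dir: Path) -> dict:
        anchor = self.cfg.simulation.marks[0]
        sets = [
            self._consensus[(anchor, tp)] for tp in self.cfg.simulation.timepoints
        ]
        self._merged = merge_conditions(sets)
        frags = self.study.fragments()
        conditions = dict(self.study.counts.conditions)
        cm = count_fragments(frags, self._merged, conditions)
        genome_sizes = {c: len(s) for c, s in self.study.genome.items()}
        cm.norm_factors = bin_tmm_factors(frags, genome_sizes, self.cfg.bin_size)[
            cm.samples
        ]
        self._counts = cm
        mio.write_counts(
            stage_dir / "counts.tsv", cm.counts, cm.library_sizes, cm.norm_factors
        )
        return {"merged_peaks": len(self._merged), "samples": len(cm.samples)}

    def stage_diffbind(self, stage_dir: Path) -> dict:
        tps = list(self.cfg.simulation.timepoints)
        self._diffbind = {}
        n_sig_union = set()
        for i in range(len(tps)):
            for j in range(i + 1, len(tps)):
                res = differential_binding(self._counts, tps[i], tps[j])
                self._diffbind[(tps[i], tps[j])] = res
                _write_df(
                    stage_dir / f"{tps[i]}_vs_{tps[j]}.tsv",
                    res.reset_index(),
                )
                n_sig_union |= set(res.index[res.fdr < self.cfg.fdr])
        self._db_significant = sorted(n_sig_union)
        _write_json(
            stage_dir / "summary.json",
            {
                "fdr": self.cfg.fdr,
                "significant_peaks_any_contrast": len(n_sig_union),
                "contrasts": [f"{a}_vs_{b}" for a, b in self._diffbind],
            },
        )
        return {"contrasts": len(self._diffbind), "significant": len(n_sig_union)}

    def stage_correlate(self, stage_dir: Path) -> dict:
        # DB promoter peaks of protein-coding genes vs expression
        ivs = [m.interval for m in self._merged]
        assigns = assign_features(
            ivs, self.study.genes, self.cfg.promoter_window, self.cfg.enhancer_window
        )
        coding = {
            g.gene_id for g in self.study.genes if g.biotype == "protein_coding"
        }
        sig = set(self._db_significant)
        rows = [
            {"peak_id": m.peak_id, "gene_id": a.gene_id, "start": m.interval.start}
            for m, a in zip(self._merged, assigns)
            if a.feature_class is FeatureClass.PROMOTER
            and a.gene_id in coding
            and m.peak_id in sig
        ]
        peak_gene_map = pd.DataFrame(rows, columns=["peak_id", "gene_id", "start"])
        binding = _binding_by_timepoint(self._counts, self.cfg.simulation.timepoints)
        expression = mio.read_expression(self.out / "inputs" / "expression.tsv")
        part = correlate_binding_expression(
            binding,
            expression,
            peak_gene_map,
            self.cfg.pos_threshold,
            self.cfg.neg_threshold,
        )
        _write_df(stage_dir / "pairs.tsv", part.pairs)
        _write_df(stage_dir / "genes.tsv", part.genes)
        n_by = part.genes.corr_class.value_counts().to_dict()
        _write_json(
            stage_dir / "summary.json",
            {
                "db_promoter_peaks": len(peak_gene_map),
                "genes_positive": int(n_by.get("positive", 0)),
                "genes_negative": int(n_by.get("negative", 0)),
                "genes_neutral": int(n_by.get("neutral", 0)),
            },
        )
        self._correlation = part
        return {"db_promoter_peaks": len(peak_gene_map)}

    def stage_cooccupancy(self, stage_dir: Path) -> dict:
        peak_sets = {
            (mark, tp): cs.intervals for (mark, tp), cs in self._consensus.items()
        }
        ledger = build_occupancy_ledger(
            peak_sets,
            self.study.genes,
            self.cfg.promoter_window,
            marks=list(self.cfg.simulation.marks),
            timepoints=list(self.cfg.simulation.timepoints),
        )
        _write_df(stage_dir / "ledger.tsv", ledger.to_long())
        fractions = cooccupancy_fractions(ledger, self.cfg.simulation.marks[0])
        _write_df(stage_dir / "fractions.tsv", fractions)
        _write_df(stage_dir / "flows.tsv", transition_flows(ledger))
        self._ledger = ledger
        return {"genes": len(ledger.gene_ids)}

    def stage_colocalize(self, stage_dir: Path) -> dict:
        anchor = self.cfg.simulation.marks[0]
        other = self.cfg.simulation.marks[1]
        tp = self.cfg.simulation.timepoints[-1]
        query = self._consensus[(anchor, tp)].intervals
        reference = self._consensus[(other, tp)].intervals
        assigns = assign_features(
            query, self.study.genes, self.cfg.promoter_window,
            self.cfg.enhancer_window,
        )
        report = colocalization_fraction(query, reference, assigns)
        report["query"] = f"{anchor}:{tp}"
        report["reference"] = f"{other}:{tp}"
        _write_json(stage_dir / "colocalization.json", report)
        return {"query_peaks": len(query)}

    def stage_motifs(self, stage_dir: Path) -> dict:
        anchor = self.cfg.simulation.marks[0]
        tp = self.cfg.simulation.timepoints[-1]
        genome = mio.read_fasta(self.out / "inputs" / "genome.fa")
        mark_peaks = self._consensus[(anchor, tp)].intervals
        from .intervals import any_overlap_flags
        from .motifs import build_control_regions

        promoters = {g.gene_id: g.promoter(self.cfg.promoter_window)
                     for g in self.study.genes}
        marked_flags = dict(
            zip(
                promoters,
                any_overlap_flags(list(promoters.values()), mark_peaks),
            )
        )
        fp = self.study.footprints
        fg_iv = [
            GenomicInterval(r.chrom, r.start, r.end)
            for r in fp.itertuples()
            if marked_flags.get(r.gene_id, False)
        ]
        bg_parents = build_control_regions(
            [v for k, v in promoters.items() if not marked_flags[k]], mark_peaks
        )
        bg_parent_genes = {
            k for k, v in promoters.items()
            if not marked_flags[k]
        }
        bg_iv = [
            GenomicInterval(r.chrom, r.start, r.end)
            for r in fp.itertuples()
            if r.gene_id in bg_parent_genes
        ]
        fg_seqs = extract_sequences(fg_iv, genome)
        bg_seqs = extract_sequences(bg_iv, genome)
        pwms = mio.read_meme_motifs(self.out / "inputs" / "motifs.meme")
        res = enrich_motifs(fg_seqs, bg_seqs, pwms, scan_p=self.cfg.scan_p)
        _write_df(stage_dir / "enrichment.tsv", res)
        fg_gc, _ = gc_content(fg_seqs)
        bg_gc, _ = gc_content(bg_seqs)
        _write_json(
            stage_dir / "gc_summary.json",
            {
                "foreground_regions": len(fg_seqs),
                "control_regions": len(bg_seqs),
                "foreground_gc": round(fg_gc, 6),
                "control_gc": round(bg_gc, 6),
                "significant_motifs": int((res.bh_q < self.cfg.motif_fdr).sum()),
            },
        )
        self._motif_result = res
        return {"fg_regions": len(fg_seqs), "bg_regions": len(bg_seqs)}

    def stage_tissues(self, stage_dir: Path) -> dict:
        occ = pd.read_csv(
            self.out / "inputs" / "tissue_occupancy.tsv", sep="\t", index_col=0
        ).astype(bool)
        sim = similarity(occ)
        _write_df(stage_dir / "phi.tsv", sim.phi, index=True)
        labels = ward_cluster(sim, self.cfg.cut_k)
        _write_df(stage_dir / "clusters.tsv", labels.rename_axis("tissue").reset_index())
        (stage_dir / "linkage.nwk").write_text(linkage_newick(sim) + "\n")
        _write_df(stage_dir / "upset.tsv", upset_counts(occ))
        return {"tissues": occ.shape[1]}

    # -------------------------------------------------------------- driver

    def run(self) -> dict:
        """Execute every stage in order.

        All stages are deterministic functions of the inputs, so a rerun
        (including a resume after deleting any stage directory) rewrites
        byte-identical outputs; regeneration is therefore always safe.
        """
        self.out.mkdir(parents=True, exist_ok=True)
        self.prepare_inputs()
        manifest_stages = []
        for name in STAGES:
            stage_dir = self.out / name
            stage_dir.mkdir(exist_ok=True)
            records = getattr(self, f"stage_{name}")(stage_dir)
            outputs = {
                str(p.relative_to(self.out)): _sha256(p)
                for p in sorted(stage_dir.glob("*"))
                if p.is_file()
            }
            manifest_stages.append(
                {"name": name, "records": records, "outputs": outputs}
            )
        manifest = {
            "stages": manifest_stages,
            "n_stages": len(manifest_stages),
            "seed": self.cfg.seed,
            "inputs": {
                str(p.relative_to(self.out)): _sha256(p)
                for p in sorted((self.out / "inputs").rglob("*"))
                if p.is_file()
            },
        }
        _write_json(self.out / "manifest.json", manifest)
        return manifest


def _binding_by_timepoint(counts, timepoints) -> pd.DataFrame:
    cpm = counts.cpm()
    out = {}
    for tp in timepoints:
        cols = [s for s in cpm.columns if counts.conditions[s] == tp]
        out[tp] = cpm[cols].mean(axis=1)
    return pd.DataFrame(out)


def correlate_study(study, fdr: float = 0.01, pos: float = 0.8, neg: float = -0.8):
    """In-memory binding-expression partition of a synthetic study.

    Mirrors the pipeline's correlate stage: differential binding across
    all ordered timepoint pairs, restriction to FDR-significant promoter
    peaks of protein-coding genes, then Pearson partitioning against the
    expression matrix.  Returns (CorrelationPartition, n_db_promoter_peaks).
    """
    tps = list(study.config.timepoints)
    sig: set = set()
    for i in range(len(tps)):
        for j in range(i + 1, len(tps)):
            res = differential_binding(study.counts, tps[i], tps[j])
            sig |= set(res.index[res.fdr < fdr])
    ivs = [m.interval for m in study.merged_peaks]
    assigns = assign_features(ivs, study.genes)
    coding = {g.gene_id for g in study.genes if g.biotype == "protein_coding"}
    rows = [
        {"peak_id": m.peak_id, "gene_id": a.gene_id, "start": m.interval.start}
        for m, a in zip(study.merged_peaks, assigns)
        if a.feature_class is FeatureClass.PROMOTER
        and a.gene_id in coding
        and m.peak_id in sig
    ]
    peak_gene_map = pd.DataFrame(rows, columns=["peak_id", "gene_id", "start"])
    binding = _binding_by_timepoint(study.counts, tps)
    part = correlate_binding_expression(
        binding, study.expression, peak_gene_map, pos, neg
    )
    return part, len(peak_gene_map)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the provenance manifest."""
    return PipelineRun(config).run()
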