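"""Seeded generator of a miniature multi-omics study with planted truth.

The generator emulates the inputs of the whole pipeline on a toy genome:

* a two-chromosome genome with GC-elevated promoters, genes laid out on
  a fixed slot grid (both strands represented) with a spacer tail per
  chromosome reserved for replicate-specific noise peaks;
* per-mark / per-timepoint / per-replicate peak calls with positional
  jitter, dropout, q-values above or below the consensus threshold, and
  singleton noise peaks that can never reach 2-of-n support;
* NB-distributed fragment counts over the merged mark loci, with planted
  differential binding and developmental trajectories;
* expression trajectories with planted positive / negative / null
  correlation classes tied to promoter binding;
* accessible footprints inside promoters with a GC-rich motif planted at
  a high rate in marked promoters and a low rate in unmarked controls;
* a multi-tissue promoter-occupancy matrix with block sharing structure.

Everything flows from one integer seed through a fixed
``numpy.random.SeedSequence`` fan-out (children in the order genome,
occupancy, peaks, counts, expression, motifs, tissues, fragments), so
each artifact regenerates identically and stages can be rerun alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import MergedPeak, ReplicatePeak
from .diffbind import CountMatrix
from .genes import GeneModel
from .intervals import GenomicInterval
from .motifs import PWM

_BASES = np.array(list("ACGT"))

# gene slot layout, oriented coordinates relative to the TSS
_SLOT_LEAD = 150  # inter-slot gap
_SLOT_UP = 1400  # bases reserved upstream of the TSS (enhancer + promoter)
_SLOT_DOWN = 800  # maximal gene length
SLOT_SIZE = _SLOT_LEAD + _SLOT_UP + _SLOT_DOWN
_GENE_LEN = (700, 800)
_PROMOTER_LOCUS = (-600, 300)
_ENHANCER_LOCUS = (-1320, -1060)
_COMARK_SHIFT = 40  # per-mark stagger of promoter loci
_UNOCCUPIED_LEVEL = 0.15
_NOISE_SLOT_SPACING = 500
_NOISE_PEAK_WIDTH = 200


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic multi-omics experiment."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_genes: int = 400
    timepoints: tuple[str, ...] = ("P4", "P10", "P21", "P28")
    marks: tuple[str, ...] = ("H3K18La", "H3K27Ac", "H3K4me3")
    replicates: int = 3
    peak_jitter_sd: float = 20.0
    peak_dropout_prob: float = 0.1
    noise_peak_rate: float = 0.05
    nb_dispersion: float = 0.1
    planted_db_fraction: float = 0.2
    fold_change: float = 4.0
    corr_class_fractions: tuple[float, float, float] = (0.25, 0.15, 0.60)
    corr_fold: float = 6.0
    expression_noise_sd: float = 0.15
    promoter_gc: float = 0.6
    background_gc: float = 0.4
    motif_plant_rate_fg: float = 0.4
    motif_plant_rate_bg: float = 0.05
    count_base_mean: float = 100.0
    library_factor_sd: float = 0.15
    max_frip: float = 0.5  # peak fraction of the library at the deepest signal
    occupancy_rates: tuple[float, ...] = (0.55, 0.60, 0.62, 0.68)
    comark_rates: tuple[float, ...] = (0.62, 0.72, 0.82, 0.92)
    comark_background_rate: float = 0.30
    extra_locus_prob: float = 0.3  # enhancer / gene-body loci per gene
    noncoding_fraction: float = 0.1
    tissue_blocks: tuple[tuple[str, ...], ...] = (
        ("brain", "cortex", "retina"),
        ("heart", "kidney", "liver"),
    )
    tissue_core_fraction: float = 0.25
    tissue_block_fraction: float = 0.30
    tissue_in_rate: float = 0.90
    tissue_out_rate: float = 0.05
    tissue_noise_flip: float = 0.02

    def __post_init__(self) -> None:
        probs = [
            self.peak_dropout_prob,
            self.motif_plant_rate_fg,
            self.motif_plant_rate_bg,
            self.promoter_gc,
            self.background_gc,
            self.comark_background_rate,
            self.extra_locus_prob,
            self.tissue_in_rate,
            self.tissue_out_rate,
            self.tissue_noise_flip,
            *self.occupancy_rates,
            *self.comark_rates,
            *self.corr_class_fractions,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if sum(self.corr_class_fractions) > 1.0 + 1e-9:
            raise ValueError("corr_class_fractions must sum to <= 1")
        if len(self.occupancy_rates) < len(self.timepoints) or len(
            self.comark_rates
        ) < len(self.timepoints):
            raise ValueError("occupancy/comark rate schedules shorter than timepoints")
        if any(
            a > b
            for a, b in zip(self.occupancy_rates, self.occupancy_rates[1:])
        ):
            raise ValueError("occupancy_rates must be non-decreasing (onset model)")

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(asdict(self)), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        for key in ("timepoints", "marks", "corr_class_fractions",
                    "occupancy_rates", "comark_rates"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "tissue_blocks" in raw:
            raw["tissue_blocks"] = tuple(tuple(b) for b in raw["tissue_blocks"])
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class GroundTruth:
    """Planted truth consistent with the emitted files."""

    gene_table: pd.DataFrame  # gene_id, corr_class, onset, has_enhancer, has_body
    occupancy: np.ndarray  # genes x timepoints x marks (gene order = gene_table)
    peak_table: pd.DataFrame  # peak_id, gene_id, kind, is_db, per-timepoint traj
    planted_footprints: pd.DataFrame  # footprint coords, role, motif_planted
    tissue_labels: pd.Series | None = None


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    names = [
        "genome",
        "occupancy",
        "peaks",
        "counts",
        "expression",
        "motifs",
        "tissues",
        "fragments",
    ]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ------------------------------------------------------------------- genome


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def simulate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome plus gene models on the slot grid.

    Promoter windows ([-1000, +500) around each TSS) are resampled at
    ``promoter_gc``; the remainder is ``background_gc``.  Raises when the
    requested genes cannot be placed without overlap.
    """
    rng = _rngs(config.seed)["genome"]
    return _simulate_genome_with(rng, config)


def _simulate_genome_with(rng, config):
    n_per = -(-config.n_genes // config.n_chroms)
    if n_per * SLOT_SIZE > config.chrom_length:
        raise ValueError(
            f"cannot place {n_per} genes of slot {SLOT_SIZE} bp on a "
            f"{config.chrom_length} bp chromosome; enlarge the genome"
        )
    genome_arr: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []
    gi = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        genome_arr[chrom] = _random_seq(rng, config.chrom_length, config.background_gc)
        for s in range(n_per):
            if gi >= config.n_genes:
                break
            slot_start = s * SLOT_SIZE
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(_GENE_LEN[0], _GENE_LEN[1] + 1))
            if strand == "+":
                tss = slot_start + _SLOT_LEAD + _SLOT_UP
                tx_start, tx_end = tss, tss + length
            else:
                tss = slot_start + _SLOT_LEAD + _SLOT_DOWN
                tx_start, tx_end = tss - length, tss
            biotype = (
                "lincRNA"
                if rng.random() < config.noncoding_fraction
                else "protein_coding"
            )
            gi += 1
            genes.append(
                GeneModel(
                    gene_id=f"g{gi:04d}",
                    symbol=f"Gene{gi}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    biotype=biotype,
                )
            )
    strands = {g.strand for g in genes}
    if strands != {"+", "-"} and config.n_genes >= 10:  # pragma: no cover
        # vanishingly unlikely; regenerate the strand of the last gene
        g = genes[-1]
        other = ("+" if g.strand == "-" else "-")
        genes[-1] = GeneModel(g.gene_id, g.chrom, other, g.tx_start, g.tx_end,
                              g.symbol, g.biotype)
    for g in genes:
        win = g.promoter()
        genome_arr[g.chrom][win.start : win.end] = _random_seq(
            rng, win.length, config.promoter_gc
        )
    genome = {c: "".join(_BASES[a]) for c, a in genome_arr.items()}
    return genome, genes


def _noise_slots(config: SimulationConfig) -> list[GenomicInterval]:
    """Candidate windows in the per-chromosome tail reserved for noise peaks."""
    n_per = -(-config.n_genes // config.n_chroms)
    used = n_per * SLOT_SIZE
    slots = []
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        pos = used + _NOISE_SLOT_SPACING
        while pos + _NOISE_PEAK_WIDTH + _NOISE_SLOT_SPACING < config.chrom_length:
            slots.append(GenomicInterval(chrom, pos, pos + _NOISE_PEAK_WIDTH))
            pos += _NOISE_PEAK_WIDTH + _NOISE_SLOT_SPACING
    return slots


# -------------------------------------------------------------- truth tables


def _ramp(fold: float, n: int) -> np.ndarray:
    if n == 1:
        return np.array([1.0])
    return fold ** (np.arange(n) / (n - 1))


def _plan_truth(rngs, config: SimulationConfig, genes: list[GeneModel]):
    """Gene classes, occupancy tensor, loci and per-locus trajectories."""
    rng = rngs["occupancy"]
    T = len(config.timepoints)
    n = len(genes)
    coding = np.array([g.biotype == "protein_coding" for g in genes])

    # correlation classes among protein-coding genes
    classes = np.array(["null"] * n, dtype=object)
    coding_idx = np.flatnonzero(coding)
    perm = rng.permutation(coding_idx)
    n_pos = int(round(config.corr_class_fractions[0] * len(coding_idx)))
    n_neg = int(round(config.corr_class_fractions[1] * len(coding_idx)))
    classes[perm[:n_pos]] = "positive"
    classes[perm[n_pos : n_pos + n_neg]] = "negative"
    classes[~coding] = "noncoding"

    # anchor-mark promoter occupancy: onset model for null/noncoding genes,
    # always-on for correlation-class genes (their binding trajectory is the
    # planted developmental ramp)
    rates = np.array(config.occupancy_rates[:T])
    u = rng.random(n)
    anchor = u[:, None] < rates[None, :]
    anchor[np.isin(classes, ["positive", "negative"])] = True
    onset = np.where(anchor.any(axis=1), anchor.argmax(axis=1), -1)

    # co-marks conditional on the anchor
    occupancy = np.zeros((n, T, len(config.marks)), dtype=bool)
    occupancy[:, :, 0] = anchor
    for mi in range(1, len(config.marks)):
        p = np.where(
            anchor,
            np.array(config.comark_rates[:T])[None, :],
            config.comark_background_rate,
        )
        occupancy[:, :, mi] = rng.random((n, T)) < p

    has_enh = rng.random(n) < config.extra_locus_prob
    has_body = rng.random(n) < config.extra_locus_prob

    gene_table = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "biotype": [g.biotype for g in genes],
            "corr_class": classes,
            "onset": onset,
            "has_enhancer": has_enh,
            "has_body": has_body,
        }
    )

    # anchor loci and their abundance trajectories
    locus_rows = []
    for i, g in enumerate(genes):
        ever = anchor[i].any()
        if not ever:
            continue
        occ = anchor[i].astype(float)
        occ[occ == 0] = _UNOCCUPIED_LEVEL
        kinds = [("promoter", _PROMOTER_LOCUS)]
        if has_enh[i]:
            kinds.append(("enhancer", _ENHANCER_LOCUS))
        if has_body[i]:
            kinds.append(("gene_body", (g.length - 200, g.length)))
        for kind, (lo, hi) in kinds:
            iv = g.window_interval(lo, hi)
            locus_rows.append(
                {
                    "gene_id": g.gene_id,
                    "kind": kind,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "corr_class": classes[i],
                    "occ_factor": occ.copy(),
                }
            )
    loci = pd.DataFrame(locus_rows)

    # planted trajectories: correlation genes ramp at the promoter; a
    # planted fraction of the enhancer / gene-body loci carries the generic
    # fold change.  Null genes keep flat promoter abundance by design:
    # expression-independent promoter trajectories would acquire chance
    # correlations at 3-4 timepoints and blur the planted partition truth.
    rng_db = rngs["counts"]
    traj = np.ones((len(loci), T))
    is_db = np.zeros(len(loci), dtype=bool)
    corr_ramp = _ramp(config.corr_fold, T)
    db_ramp = _ramp(config.fold_change, T)
    for j, row in enumerate(loci.itertuples()):
        if row.kind == "promoter" and row.corr_class in ("positive", "negative"):
            traj[j] = corr_ramp
            is_db[j] = True
        elif row.kind != "promoter" and rng_db.random() < config.planted_db_fraction:
            traj[j] = db_ramp if rng_db.random() < 0.5 else db_ramp[::-1]
            is_db[j] = True
        traj[j] = traj[j] * row.occ_factor
        if np.ptp(row.occ_factor) > 0:
            is_db[j] = True
    loci = loci.drop(columns=["occ_factor"])
    loci["is_db"] = is_db
    for t in range(T):
        loci[f"traj_{config.timepoints[t]}"] = traj[:, t]
    loci["peak_id"] = [
        f"{r.chrom}:{r.start}-{r.end}" for r in loci.itertuples()
    ]
    return gene_table, occupancy, loci


# -------------------------------------------------------------------- peaks


def _jitter(rng, iv: GenomicInterval, sd: float, chrom_len: int) -> GenomicInterval:
    if sd <= 0:
        return iv
    ds, de = np.rint(rng.normal(0.0, sd, size=2)).astype(int)
    start = max(0, iv.start + int(ds))
    end = min(chrom_len, iv.end + int(de))
    if end <= start:
        start, end = iv.start, iv.end
    return GenomicInterval(iv.chrom, start, end, iv.strand)


def _simulate_peaks_with(rngs, config, genes, gene_table, occupancy, loci):
    """Replicate narrowPeak-style calls per mark x timepoint."""
    rng = rngs["peaks"]
    T = len(config.timepoints)
    gene_index = {g.gene_id: i for i, g in enumerate(genes)}
    gene_by_id = {g.gene_id: g for g in genes}
    slots = _noise_slots(config)
    out: dict[tuple[str, str], list[list[ReplicatePeak]]] = {}
    for mi, mark in enumerate(config.marks):
        for ti, tp in enumerate(config.timepoints):
            # true loci of this mark at this timepoint
            if mi == 0:
                true_loci = [
                    GenomicInterval(r.chrom, r.start, r.end)
                    for r in loci.itertuples()
                    if occupancy[gene_index[r.gene_id], ti, 0]
                ]
            else:
                shift = _COMARK_SHIFT * mi
                true_loci = []
                for gid, occ in zip(gene_table.gene_id, occupancy[:, ti, mi]):
                    if not occ:
                        continue
                    g = gene_by_id[gid]
                    iv = g.window_interval(
                        _PROMOTER_LOCUS[0] - shift, _PROMOTER_LOCUS[1] - shift
                    )
                    true_loci.append(iv)
            reps: list[list[ReplicatePeak]] = []
            n_noise_each = rng.poisson(
                config.noise_peak_rate * max(len(true_loci), 1),
                size=config.replicates,
            )
            slot_order = rng.permutation(len(slots))
            cursor = 0
            for r in range(config.replicates):
                peaks: list[ReplicatePeak] = []
                rep_id = f"rep{r + 1}"
                for iv in true_loci:
                    if rng.random() < config.peak_dropout_prob:
                        continue
                    jiv = _jitter(rng, iv, config.peak_jitter_sd, config.chrom_length)
                    peaks.append(
                        ReplicatePeak(
                            jiv,
                            neglog10_q=float(rng.uniform(8.0, 30.0)),
                            signal=float(rng.lognormal(2.0, 0.5)),
                            replicate_id=rep_id,
                        )
                    )
                # singleton noise peaks: disjoint slots, never shared between
                # replicates of this (mark, timepoint) grid cell
                take = min(int(n_noise_each[r]), max(len(slots) - cursor, 0))
                for k in range(take):
                    slot = slots[slot_order[cursor + k]]
                    peaks.append(
                        ReplicatePeak(
                            _jitter(rng, slot, config.peak_jitter_sd,
                                    config.chrom_length),
                            neglog10_q=float(rng.uniform(6.5, 12.0)),
                            signal=float(rng.lognormal(1.0, 0.5)),
                            replicate_id=rep_id,
                        )
                    )
                cursor += take
                # sub-threshold calls exercising the q-value filter
                n_lowq = int(rng.poisson(0.02 * max(len(true_loci), 1)))
                take = min(n_lowq, max(len(slots) - cursor, 0))
                for k in range(take):
                    slot = slots[slot_order[cursor + k]]
                    peaks.append(
                        ReplicatePeak(
                            slot,
                            neglog10_q=float(rng.uniform(0.5, 5.5)),
                            signal=float(rng.lognormal(0.5, 0.5)),
                            replicate_id=rep_id,
                        )
                    )
                cursor += take
                peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
                peaks = [
                    ReplicatePeak(
                        p.interval,
                        p.neglog10_q,
                        p.signal,
                        p.replicate_id,
                        name=f"{mark}_{tp}_{p.replicate_id}_p{i + 1}",
                    )
                    for i, p in enumerate(peaks)
                ]
                reps.append(peaks)
            out[(mark, tp)] = reps
    return out


# -------------------------------------------------------------------- counts


def _simulate_counts_with(rngs, config, loci):
    """NB counts over the merged anchor loci, one sample per
    (timepoint, replicate)."""
    rng = rngs["counts"]
    T = len(config.timepoints)
    order = np.lexsort((loci.start.values, loci.chrom.values))
    loci = loci.iloc[order].reset_index(drop=True)
    base = rng.lognormal(np.log(config.count_base_mean), 0.4, size=len(loci))
    samples = []
    conditions = {}
    lib_factors = {}
    for tp in config.timepoints:
        for r in range(config.replicates):
            s = f"{tp}_rep{r + 1}"
            samples.append(s)
            conditions[s] = tp
            lib_factors[s] = float(rng.lognormal(0.0, config.library_factor_sd))
    counts = np.zeros((len(loci), len(samples)), dtype=np.int64)
    phi = config.nb_dispersion
    for j, s in enumerate(samples):
        ti = list(config.timepoints).index(conditions[s])
        traj = loci[f"traj_{config.timepoints[ti]}"].values
        mu = base * traj * lib_factors[s]
        if phi <= 0:
            counts[:, j] = rng.poisson(mu)
        else:
            r_nb = 1.0 / phi
            counts[:, j] = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
    peak_ids = loci.peak_id.tolist()
    peak_total = counts.sum(axis=0)
    # sequencing depth is independent of signal: fixed expected library per
    # depth factor, so the fraction of reads in peaks (FRiP) grows as marks
    # accumulate while flat loci keep constant expected CPM
    expected_peak = max(
        float((base[:, None] * np.stack(
            [loci[f"traj_{tp}"].values for tp in config.timepoints], axis=1
        )).sum(axis=0).max()),
        1.0,
    )
    depth0 = expected_peak / max(config.max_frip, 1e-3)
    lib_target = np.array([depth0 * lib_factors[s] for s in samples])
    n_bg = np.maximum(np.rint(lib_target).astype(int) - peak_total, 0)
    lib = pd.Series(peak_total + n_bg, index=samples, dtype=float)
    cm = CountMatrix(
        pd.DataFrame(counts, index=peak_ids, columns=samples),
        lib,
        pd.Series(conditions)[samples],
    )
    merged = [
        MergedPeak(
            GenomicInterval(r.chrom, r.start, r.end), tuple(config.timepoints)
        )
        for r in loci.itertuples()
    ]
    return cm, merged, loci, n_bg


# ---------------------------------------------------------------- expression


def _simulate_expression_with(rngs, config, gene_table):
    rng = rngs["expression"]
    T = len(config.timepoints)
    ln_ramp = np.log(_ramp(config.corr_fold, T))
    rows = {}
    for rec in gene_table.itertuples():
        ln_base = rng.normal(np.log(20.0), 0.7)
        eps = rng.normal(0.0, config.expression_noise_sd, size=T)
        if rec.corr_class == "positive":
            ln_e = ln_base + ln_ramp + eps
        elif rec.corr_class == "negative":
            ln_e = ln_base - ln_ramp + eps
        else:
            ln_e = ln_base + eps
        rows[rec.gene_id] = np.exp(ln_e)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(config.timepoints)
    ).rename_axis("gene_id")


# ------------------------------------------------------------------- motifs


def toy_pwms() -> list[PWM]:
    """Packaged toy motif set: one sharp GC-box (the plantable motif) and
    four decoys of differing composition."""

    def sharp(motif_id: str, consensus: str, p: float = 0.95) -> PWM:
        m = np.full((4, len(consensus)), (1 - p) / 3)
        for j, b in enumerate(consensus):
            m["ACGT".index(b), j] = p
        return PWM(motif_id=motif_id, matrix=m, pseudocount=0.0)

    return [
        sharp("GCBOX_TOY", "GGGGCGGGG"),
        sharp("KLF_TOY", "CCACACCCA", p=0.85),
        sharp("TATA_TOY", "TATAAATA", p=0.85),
        sharp("EBOX_TOY", "CACGTGAC", p=0.85),
        sharp("ZIC_TOY", "CCCGCTGGG", p=0.85),
    ]


PLANTED_MOTIF = "GCBOX_TOY"


def _sample_instance(rng, pwm: PWM) -> str:
    return "".join(
        "ACGT"[rng.choice(4, p=pwm.matrix[:, j])] for j in range(pwm.width)
    )


def _simulate_footprints_with(rngs, config, genes, gene_table, occupancy, genome):
    """Footprints in every promoter; motif instances written into the
    genome at the foreground rate for marked promoters (anchor mark at
    the last timepoint) and the background rate for unmarked ones."""
    import warnings

    rng = rngs["motifs"]
    pwm = [p for p in toy_pwms() if p.motif_id == PLANTED_MOTIF][0]
    arr = {c: np.array(list(s)) for c, s in genome.items()}
    last = occupancy.shape[1] - 1
    marked = dict(zip(gene_table.gene_id, occupancy[:, last, 0]))
    rows = []
    for g in genes:
        parent = g.promoter()
        n_fp = int(rng.integers(1, 4))
        role = "foreground" if marked[g.gene_id] else "control"
        rate = (
            config.motif_plant_rate_fg
            if role == "foreground"
            else config.motif_plant_rate_bg
        )
        for _ in range(n_fp):
            length = int(rng.integers(15, 31))
            if length > parent.length:  # pragma: no cover - promoters are 1500 bp
                warnings.warn("footprint clipped to its parent region")
                length = parent.length
            start = parent.start + int(rng.integers(0, parent.length - length + 1))
            fp = GenomicInterval(parent.chrom, start, start + length)
            planted = False
            if rng.random() < rate and length >= pwm.width:
                inst = _sample_instance(rng, pwm)
                off = int(rng.integers(0, length - pwm.width + 1))
                arr[fp.chrom][fp.start + off : fp.start + off + pwm.width] = list(inst)
                planted = True
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "chrom": fp.chrom,
                    "start": fp.start,
                    "end": fp.end,
                    "role": role,
                    "motif_planted": planted,
                }
            )
    genome = {c: "".join(a) for c, a in arr.items()}
    return pd.DataFrame(rows), genome


def simulate_motif_sequences(
    n_fg: int = 300,
    n_bg: int = 300,
    gc: float = 0.6,
    plant_rate_fg: float = 0.4,
    plant_rate_bg: float = 0.05,
    pwm: PWM | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Footprint-sized sequence sets with a motif planted at two rates.

    Both sets share the same GC composition (class-matched controls);
    returns (fg, bg, fg_planted flags, bg_planted flags).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if pwm is None:
        pwm = [p for p in toy_pwms() if p.motif_id == PLANTED_MOTIF][0]

    def make(n, rate):
        seqs, flags = [], np.zeros(n, dtype=bool)
        for i in range(n):
            length = int(rng.integers(15, 31))
            seq = list(_BASES[_random_seq(rng, length, gc)])
            if rng.random() < rate and length >= pwm.width:
                inst = _sample_instance(rng, pwm)
                off = int(rng.integers(0, length - pwm.width + 1))
                seq[off : off + pwm.width] = list(inst)
                flags[i] = True
            seqs.append("".join(seq))
        return seqs, flags

    fg, fg_flags = make(n_fg, plant_rate_fg)
    bg, bg_flags = make(n_bg, plant_rate_bg)
    return fg, bg, fg_flags, bg_flags


# ------------------------------------------------------------------- tissues


def simulate_tissue_matrix(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Boolean gene x tissue occupancy with planted block structure.

    Returns (matrix, tissue -> block label).  Shared-core genes are
    occupied everywhere; block genes at ``tissue_in_rate`` inside their
    block and ``tissue_out_rate`` outside; the remainder at the out-rate;
    finally independent noise flips.
    """
    rng = _rngs(config.seed)["tissues"]
    tissues = [t for block in config.tissue_blocks for t in block]
    block_of = pd.Series(
        {
            t: f"block{i + 1}"
            for i, block in enumerate(config.tissue_blocks)
            for t in block
        }
    )
    n = config.n_genes
    gene_ids = [f"g{i + 1:04d}" for i in range(n)]
    m = np.zeros((n, len(tissues)), dtype=bool)
    u = rng.random(n)
    core = u < config.tissue_core_fraction
    nb = len(config.tissue_blocks)
    assign = np.full(n, -1)
    for b in range(nb):
        lo = config.tissue_core_fraction + b * config.tissue_block_fraction
        assign[(u >= lo) & (u < lo + config.tissue_block_fraction)] = b
    for j, t in enumerate(tissues):
        b = int(block_of[t].removeprefix("block")) - 1
        p = np.where(
            core,
            1.0,
            np.where(assign == b, config.tissue_in_rate, config.tissue_out_rate),
        )
        m[:, j] = rng.random(n) < p
    flips = rng.random(m.shape) < config.tissue_noise_flip
    m ^= flips
    return (
        pd.DataFrame(m, index=gene_ids, columns=tissues),
        block_of,
    )


# -------------------------------------------------------------------- study


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    truth: GroundTruth
    replicate_peaks: dict[tuple[str, str], list[list[ReplicatePeak]]]
    counts: CountMatrix
    merged_peaks: list[MergedPeak]
    expression: pd.DataFrame
    pwms: list[PWM]
    footprints: pd.DataFrame
    tissue_occupancy: pd.DataFrame
    tissue_blocks: pd.Series
    _n_background_fragments: np.ndarray = field(repr=False, default=None)

    def binding_by_timepoint(self) -> pd.DataFrame:
        """Replicate-averaged normalized log2 CPM per peak and timepoint."""
        cpm = self.counts.cpm()
        out = {}
        for tp in self.config.timepoints:
            cols = [s for s in cpm.columns if self.counts.conditions[s] == tp]
            out[tp] = cpm[cols].mean(axis=1)
        return pd.DataFrame(out)

    def fragments(self) -> dict[str, list[GenomicInterval]]:
        """Materialize per-sample fragment intervals consistent with the
        count matrix (deterministic for the study seed; cached)."""
        if getattr(self, "_fragments_cache", None) is not None:
            return self._fragments_cache
        rng = _rngs(self.config.seed)["fragments"]
        peaks = [m.interval for m in self.merged_peaks]
        starts = np.array([p.start for p in peaks])
        ends = np.array([p.end for p in peaks])
        chroms = [p.chrom for p in peaks]
        genome_len = {c: len(s) for c, s in self.genome.items()}
        chrom_names = sorted(genome_len)
        by_chrom = {
            c: (
                np.sort(starts[[i for i, ch in enumerate(chroms) if ch == c]]),
                np.sort(ends[[i for i, ch in enumerate(chroms) if ch == c]]),
            )
            for c in chrom_names
        }
        out: dict[str, list[GenomicInterval]] = {}
        for j, sample in enumerate(self.counts.samples):
            frags: list[GenomicInterval] = []
            col = self.counts.counts[sample].values
            for i in range(len(peaks)):
                k = int(col[i])
                if k == 0:
                    continue
                mids = rng.integers(starts[i], ends[i], size=k)
                lens = rng.integers(80, 161, size=k)
                for mid, ln in zip(mids, lens):
                    s0 = max(0, int(mid) - int(ln) // 2)
                    frags.append(
                        GenomicInterval(chroms[i], s0, s0 + int(ln))
                    )
            # background fragments with midpoints outside every peak
            n_bg = int(self._n_background_fragments[j])
            placed = 0
            while placed < n_bg:
                take = max(n_bg - placed, 16)
                ci = rng.integers(0, len(chrom_names), size=take)
                pos = rng.integers(0, min(genome_len.values()), size=take)
                lens = rng.integers(80, 161, size=take)
                for c, mid, ln in zip(ci, pos, lens):
                    chrom = chrom_names[int(c)]
                    cs, ce = by_chrom[chrom]
                    idx = int(np.searchsorted(cs, mid, side="right")) - 1
                    if idx >= 0 and mid < ce[idx]:
                        continue
                    s0 = max(0, int(mid) - int(ln) // 2)
                    frags.append(GenomicInterval(chrom, s0, s0 + int(ln)))
                    placed += 1
                    if placed >= n_bg:
                        break
            out[sample] = frags
        self._fragments_cache = out
        return out


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate the full synthetic multi-omics study for one seed."""
    rngs = _rngs(config.seed)
    genome, genes = _simulate_genome_with(rngs["genome"], config)
    gene_table, occupancy, loci = _plan_truth(rngs, config, genes)
    replicate_peaks = _simulate_peaks_with(
        rngs, config, genes, gene_table, occupancy, loci
    )
    counts, merged, loci, n_bg = _simulate_counts_with(rngs, config, loci)
    expression = _simulate_expression_with(rngs, config, gene_table)
    footprints, genome = _simulate_footprints_with(
        rngs, config, genes, gene_table, occupancy, genome
    )
    tissue_occ, tissue_blocks = simulate_tissue_matrix(config)
    truth = GroundTruth(
        gene_table=gene_table,
        occupancy=occupancy,
        peak_table=loci,
        planted_footprints=footprints,
        tissue_labels=tissue_blocks,
    )
    return SyntheticStudy(
        config=config,
        genome=genome,
        genes=genes,
        truth=truth,
        replicate_peaks=replicate_peaks,
        counts=counts,
        merged_peaks=merged,
        expression=expression,
        pwms=toy_pwms(),
        footprints=footprints,
        tissue_occupancy=tissue_occ,
        tissue_blocks=tissue_blocks,
        _n_background_fragments=n_bg,
    )


# ------------------------------------------------- focused stats benchmarks


def simulate_count_benchmark(
    n_peaks: int = 2000,
    n_per_group: int = 3,
    phi: float = 0.1,
    base_mean: float = 100.0,
    fold_change: float = 1.0,
    db_fraction: float = 0.0,
    library_factor_sd: float = 0.15,
    seed: int | np.random.Generator = 0,
    groups: tuple[str, str] = ("A", "B"),
) -> tuple[CountMatrix, np.ndarray]:
    """Two-group NB count matrix with an optional planted fold change.

    Used for calibration (fold 1 / db_fraction 0) and sensitivity
    benchmarks of the differential-binding test.  Returns the matrix and
    the boolean planted-DB indicator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = rng.lognormal(np.log(base_mean), 0.4, size=n_peaks)
    is_db = rng.random(n_peaks) < db_fraction
    direction = np.where(rng.random(n_peaks) < 0.5, 1.0, -1.0)
    fold = np.where(is_db, fold_change**direction, 1.0)
    samples = [f"{g}_rep{i + 1}" for g in groups for i in range(n_per_group)]
    conditions = {s: s.split("_")[0] for s in samples}
    lib_factor = rng.lognormal(0.0, library_factor_sd, size=len(samples))
    counts = np.zeros((n_peaks, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        mu = base * (fold if conditions[s] == groups[1] else 1.0) * lib_factor[j]
        if phi <= 0:
            counts[:, j] = rng.poisson(mu)
        else:
            r_nb = 1.0 / phi
            counts[:, j] = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
    lib = pd.Series(1e6 * lib_factor, index=samples)
    cm = CountMatrix(
        pd.DataFrame(counts, index=[f"pk{i}" for i in range(n_peaks)], columns=samples),
        lib,
        pd.Series(conditions)[samples],
    )
    return cm, is_db
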