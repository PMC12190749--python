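"""Fragment counting, TMM normalization on genome bins, NB differential
binding, BH-FDR and PCA.

The differential test is a negative-binomial likelihood-ratio test with
log(library_size * norm_factor) offsets: per peak, the NB log-likelihood
is maximized under a single-mean null and a per-group alternative, and
2*deltaLogL is referred to chi-square(1) (chi-square(k-1) for the
omnibus variant).  Dispersion is the NB overdispersion phi in
Var = mu + phi * mu^2, estimated by method of moments within groups with
optional shrinkage toward the trimmed mean across peaks; at minimal
replication the high-level entry point defaults to the trimmed-mean
common dispersion, which is what keeps the far tail of the chi-square
reference honest (see docs/methods.md).

Between-sample scale factors follow the trimmed-mean-of-M-values recipe
computed on non-overlapping 10 kb genome bins: reference sample closest
to the mean log library size, per-bin M and A values, two-sided trims of
30% (M) and 5% (A), inverse-variance weights, and a final rescaling to
geometric mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import MergedPeak
from .intervals import GenomicInterval

DISPERSION_FLOOR = 1e-4


@dataclass
class CountMatrix:
    """Peaks x samples fragment counts plus normalization state."""

    counts: pd.DataFrame  # int counts, index = peak ids, columns = samples
    library_sizes: pd.Series  # total fragments per sample (incl. outside peaks)
    conditions: pd.Series  # sample -> condition label
    norm_factors: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.norm_factors is None:
            self.norm_factors = pd.Series(1.0, index=self.counts.columns)
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        if (self.norm_factors <= 0).any():
            raise ValueError("norm factors must be positive")
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        self.conditions = self.conditions.reindex(self.counts.columns)
        self.norm_factors = self.norm_factors.reindex(self.counts.columns)
        if (
            self.library_sizes.isna().any()
            or self.conditions.isna().any()
            or self.norm_factors.isna().any()
        ):
            raise ValueError("sample metadata does not cover all count columns")
        gm = np.exp(np.mean(np.log(self.norm_factors.values)))
        if abs(gm - 1.0) > 1e-6:
            self.norm_factors = self.norm_factors / gm

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def effective_sizes(self) -> pd.Series:
        return self.library_sizes * self.norm_factors

    def cpm(self, prior: float = 0.5) -> pd.DataFrame:
        """log2 counts-per-million on effective library sizes."""
        eff = self.effective_sizes.values
        vals = np.log2(self.counts.values / eff * 1e6 + prior)
        return pd.DataFrame(vals, index=self.counts.index, columns=self.counts.columns)

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(samples)],
            self.library_sizes[list(samples)],
            self.conditions[list(samples)],
            self.norm_factors[list(samples)],
        )


# ----------------------------------------------------------------- counting


def _midpoints_by_chrom(fragments: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    by: dict[str, list[int]] = {}
    for f in fragments:
        by.setdefault(f.chrom, []).append(f.midpoint)
    return {c: np.asarray(v) for c, v in by.items()}


def count_fragments(
    fragments_per_sample: Mapping[str, Sequence[GenomicInterval]],
    peaks: Sequence[MergedPeak],
    conditions: Mapping[str, str] | None = None,
) -> CountMatrix:
    """Count, per sample, fragments whose midpoint falls inside each peak.

    Peaks must be disjoint (they come from merge_conditions), so each
    fragment midpoint lands in at most one peak.  Library size is the
    total fragment count of the sample, including fragments outside all
    peaks.
    """
    peak_ids = [p.peak_id for p in peaks]
    by_chrom_peaks: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    order: dict[str, np.ndarray] = {}
    for chrom in {p.interval.chrom for p in peaks}:
        idx = np.array(
            [i for i, p in enumerate(peaks) if p.interval.chrom == chrom]
        )
        starts = np.array([peaks[i].interval.start for i in idx])
        ends = np.array([peaks[i].interval.end for i in idx])
        o = np.argsort(starts)
        by_chrom_peaks[chrom] = (starts[o], ends[o])
        order[chrom] = idx[o]

    data = {}
    lib = {}
    for sample, frags in fragments_per_sample.items():
        if len(frags) == 0:
            raise ValueError(f"sample {sample!r} has zero fragments")
        counts = np.zeros(len(peaks), dtype=np.int64)
        for chrom, mids in _midpoints_by_chrom(frags).items():
            if chrom not in by_chrom_peaks:
                continue
            starts, ends = by_chrom_peaks[chrom]
            pos = np.searchsorted(starts, mids, side="right") - 1
            ok = (pos >= 0) & (mids < ends[np.clip(pos, 0, None)])
            hit = pos[ok]
            np.add.at(counts, order[chrom][hit], 1)
        data[sample] = counts
        lib[sample] = len(frags)
    df = pd.DataFrame(data, index=peak_ids)
    cond = pd.Series(
        {s: (conditions or {}).get(s, s) for s in fragments_per_sample}, dtype=object
    )
    return CountMatrix(df, pd.Series(lib, dtype=float), cond[df.columns])


def bin_counts(
    fragments_per_sample: Mapping[str, Sequence[GenomicInterval]],
    genome_sizes: Mapping[str, int],
    bin_size: int = 10_000,
) -> pd.DataFrame:
    """Fragment-midpoint counts in non-overlapping genome tiles."""
    bins = []
    for chrom in sorted(genome_sizes):
        n = -(-genome_sizes[chrom] // bin_size)
        bins.extend((chrom, i) for i in range(n))
    offsets = {}
    pos = 0
    for chrom in sorted(genome_sizes):
        n = -(-genome_sizes[chrom] // bin_size)
        offsets[chrom] = (pos, n)
        pos += n
    data = {}
    for sample, frags in fragments_per_sample.items():
        v = np.zeros(len(bins), dtype=np.int64)
        for chrom, mids in _midpoints_by_chrom(frags).items():
            if chrom not in genome_sizes:
                continue
            off, n = offsets[chrom]
            v[off : off + n] += np.bincount(mids // bin_size, minlength=n)[:n]
        data[sample] = v
    return pd.DataFrame(data, index=pd.MultiIndex.from_tuples(bins))


def tmm_norm_factors(
    counts: pd.DataFrame | np.ndarray,
    library_sizes: Sequence[float],
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> np.ndarray:
    """TMM scale factors from a (regions x samples) count table.

    The reference is the sample whose log library size is closest to the
    mean log library size.  For each sample, bins with nonzero counts in
    both the sample and the reference contribute M (log2 ratio of
    depth-scaled counts) and A (mean log2 abundance); M is trimmed 30%
    from each tail and A 5% from each tail, and the factor is
    2**(inverse-variance weighted mean of retained M).  Factors are
    rescaled to geometric mean 1.
    """
    y = np.asarray(counts, dtype=float)
    lib = np.asarray(library_sizes, dtype=float)
    n = y.shape[1]
    if n < 2:
        raise ValueError("TMM requires >= 2 samples")
    loglib = np.log(lib)
    ref = int(np.argmin(np.abs(loglib - loglib.mean())))
    factors = np.ones(n)
    for s in range(n):
        if s == ref:
            continue
        ok = (y[:, s] > 0) & (y[:, ref] > 0)
        ys, yr = y[ok, s], y[ok, ref]
        ps, pr = ys / lib[s], yr / lib[ref]
        M = np.log2(ps / pr)
        A = 0.5 * np.log2(ps * pr)
        w = 1.0 / (
            (lib[s] - ys) / (lib[s] * ys) + (lib[ref] - yr) / (lib[ref] * yr)
        )
        keep = np.ones(len(M), dtype=bool)
        for v, trim in ((M, m_trim), (A, a_trim)):
            lo, hi = np.quantile(v, [trim, 1 - trim])
            keep &= (v >= lo) & (v <= hi)
        if keep.sum() == 0:
            continue
        factors[s] = 2 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    return factors / np.exp(np.mean(np.log(factors)))


def bin_tmm_factors(
    fragments_per_sample: Mapping[str, Sequence[GenomicInterval]],
    genome_sizes: Mapping[str, int],
    bin_size: int = 10_000,
) -> pd.Series:
    """TMM factors computed on 10 kb genome bins (normalization only)."""
    bc = bin_counts(fragments_per_sample, genome_sizes, bin_size)
    lib = np.array([len(fragments_per_sample[s]) for s in bc.columns], dtype=float)
    return pd.Series(tmm_norm_factors(bc, lib), index=bc.columns)


# --------------------------------------------------------------- dispersion


def estimate_dispersion(
    counts: CountMatrix,
    groups: Mapping[str, Sequence[str]] | None = None,
    floor: float = DISPERSION_FLOOR,
    shrink: float = 0.3,
) -> np.ndarray:
    """Per-peak NB dispersion by method of moments on normalized counts.

    Within each group the sample mean m and variance s^2 of depth-
    normalized counts give phi = (s^2 - m) / m^2; group estimates are
    averaged, floored at 1e-4, and shrunk toward the 10%-trimmed mean
    across peaks with weight ``shrink`` on that common value.
    """
    if groups is None:
        groups = {}
        for s, c in counts.conditions.items():
            groups.setdefault(c, []).append(s)
    eff = counts.effective_sizes
    scale = np.exp(np.mean(np.log(eff.values)))
    raw = np.zeros(len(counts.counts))
    n_used = np.zeros(len(counts.counts))
    for members in groups.values():
        if len(members) < 2:
            continue
        y = counts.counts[list(members)].values / eff[list(members)].values * scale
        m = y.mean(axis=1)
        s2 = y.var(axis=1, ddof=1)
        ok = m > 0
        phi = np.zeros(len(m))
        phi[ok] = (s2[ok] - m[ok]) / m[ok] ** 2
        raw += phi
        n_used += 1
    if n_used.max() == 0:
        raise ValueError("need >= 2 samples in >= 1 group")
    raw = np.maximum(raw / np.maximum(n_used, 1), floor)
    common = common_dispersion_from(raw)
    return np.maximum((1 - shrink) * raw + shrink * common, floor)


def common_dispersion_from(per_peak: np.ndarray, trim: float = 0.1) -> float:
    """Trimmed mean of per-peak dispersion estimates."""
    lo, hi = np.quantile(per_peak, [trim, 1 - trim])
    kept = per_peak[(per_peak >= lo) & (per_peak <= hi)]
    return float(max(kept.mean(), DISPERSION_FLOOR)) if len(kept) else DISPERSION_FLOOR


def common_dispersion_mle(
    counts: CountMatrix,
    groups: Mapping[str, Sequence[str]] | None = None,
    phi_grid: tuple[float, float] = (DISPERSION_FLOOR, 5.0),
) -> float:
    """Common NB dispersion by Cox-Reid adjusted profile likelihood.

    Group means are profiled out per peak at each candidate phi and the
    summed log-likelihood is adjusted by -0.5 log of the per-group Fisher
    information (which removes the downward bias of the plain profile
    MLE at small replicate numbers).  Optimized by golden-section search
    on log phi.
    """
    if groups is None:
        groups = {}
        for s, c in counts.conditions.items():
            groups.setdefault(c, []).append(s)
    blocks = []
    for members in groups.values():
        if len(members) < 2:
            continue
        y = counts.counts[list(members)].values.astype(float)
        offs = np.log(counts.effective_sizes[list(members)].values)
        blocks.append((y[y.sum(axis=1) > 0], offs))
    if not blocks:
        raise ValueError("need >= 2 samples in >= 1 group")

    def neg_apl(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        total = 0.0
        for y, offs in blocks:
            phi_vec = np.full(len(y), phi)
            beta = _fit_log_mean(y, offs, phi_vec)
            mu = np.exp(beta[:, None] + offs[None, :])
            ll = _nb_loglik(y, mu, phi_vec)
            info = (mu / (1.0 + phi * mu)).sum(axis=1)
            total += float(np.sum(ll - 0.5 * np.log(np.maximum(info, 1e-12))))
        return -total

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        neg_apl,
        bounds=(np.log(phi_grid[0]), np.log(phi_grid[1])),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(max(np.exp(res.x), DISPERSION_FLOOR))


# --------------------------------------------------------------- NB LRT test


def _fit_log_mean(
    y: np.ndarray, offsets: np.ndarray, phi: np.ndarray, iters: int = 60
) -> np.ndarray:
    """MLE of beta in mu_s = exp(beta + offset_s), NB dispersion phi.

    The score in beta is strictly decreasing, so damped Newton from the
    depth-weighted mean converges monotonically.  Rows with all-zero
    counts get beta = -inf (mu = 0, log-likelihood 0).
    """
    tot = y.sum(axis=1)
    denom = np.exp(offsets).sum()
    beta = np.log(np.maximum(tot, 0.5) / denom)
    for _ in range(iters):
        mu = np.exp(beta[:, None] + offsets[None, :])
        W = 1.0 + phi[:, None] * mu
        f = ((y - mu) / W).sum(axis=1)
        fp = -((mu * (1.0 + phi[:, None] * y)) / W**2).sum(axis=1)
        step = f / np.where(fp == 0, -1.0, fp)
        step = np.clip(step, -4.0, 4.0)
        beta = beta - step
        if np.max(np.abs(step)) < 1e-12:
            break
    beta[tot == 0] = -np.inf
    return beta


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    r = 1.0 / phi[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = stats.nbinom.logpmf(y, r, r / (r + mu))
    ll = np.where(mu == 0, np.where(y == 0, 0.0, -np.inf), ll)
    return ll.sum(axis=1)


def nb_lrt_test(
    counts: CountMatrix,
    group_a: str,
    group_b: str,
    dispersions: np.ndarray,
) -> pd.DataFrame:
    """Two-group NB likelihood-ratio test; log2FC is group_b vs group_a.

    Offsets are log(library_size * norm_factor).  All-zero peaks are
    flagged with p = 1 and lfc = 0.  Returns one row per peak with
    p_value, BH fdr, log2_fold_change and mean normalized log-abundance.
    """
    samples_a = [s for s in counts.samples if counts.conditions[s] == group_a]
    samples_b = [s for s in counts.samples if counts.conditions[s] == group_b]
    if not samples_a or not samples_b:
        raise ValueError(f"contrast groups {group_a!r}/{group_b!r} not found")
    sel = samples_a + samples_b
    y = counts.counts[sel].values.astype(float)
    offs = np.log(counts.effective_sizes[sel].values)
    phi = np.asarray(dispersions, dtype=float)
    na = len(samples_a)

    beta0 = _fit_log_mean(y, offs, phi)
    beta_a = _fit_log_mean(y[:, :na], offs[:na], phi)
    beta_b = _fit_log_mean(y[:, na:], offs[na:], phi)

    mu0 = np.exp(beta0[:, None] + offs[None, :])
    mu0[beta0 == -np.inf] = 0.0
    ll0 = _nb_loglik(y, mu0, phi)
    mua = np.exp(beta_a[:, None] + offs[None, :na])
    mua[beta_a == -np.inf] = 0.0
    mub = np.exp(beta_b[:, None] + offs[None, na:])
    mub[beta_b == -np.inf] = 0.0
    ll1 = _nb_loglik(y[:, :na], mua, phi) + _nb_loglik(y[:, na:], mub, phi)

    stat = np.maximum(2.0 * (ll1 - ll0), 0.0)
    p = stats.chi2.sf(stat, df=1)
    all_zero = y.sum(axis=1) == 0
    p[all_zero] = 1.0

    denom_a = np.exp(offs[:na]).sum()
    denom_b = np.exp(offs[na:]).sum()
    mean_a = np.where(
        beta_a == -np.inf, 0.5 / denom_a, np.exp(beta_a)
    )
    mean_b = np.where(
        beta_b == -np.inf, 0.5 / denom_b, np.exp(beta_b)
    )
    lfc = np.log2(mean_b / mean_a)
    lfc[all_zero] = 0.0

    log_cpm = counts.cpm()[sel].values.mean(axis=1)
    return pd.DataFrame(
        {
            "peak_id": counts.counts.index,
            "log2_fold_change": lfc,
            "p_value": p,
            "fdr": bh_adjust(p),
            "mean_abundance": log_cpm,
            "all_zero": all_zero,
        }
    ).set_index("peak_id")


def nb_omnibus_test(
    counts: CountMatrix, groups: Sequence[str], dispersions: np.ndarray
) -> pd.DataFrame:
    """k-group omnibus LRT against chi-square(k-1)."""
    members = [
        [s for s in counts.samples if counts.conditions[s] == g] for g in groups
    ]
    if any(len(m) == 0 for m in members):
        raise ValueError("every omnibus group needs >= 1 sample")
    sel = [s for m in members for s in m]
    y = counts.counts[sel].values.astype(float)
    offs = np.log(counts.effective_sizes[sel].values)
    phi = np.asarray(dispersions, dtype=float)

    ll0 = _nb_loglik(
        y, np.exp(_fit_log_mean(y, offs, phi)[:, None] + offs[None, :]), phi
    )
    ll1 = np.zeros(len(y))
    i = 0
    for m in members:
        j = i + len(m)
        b = _fit_log_mean(y[:, i:j], offs[i:j], phi)
        mu = np.exp(b[:, None] + offs[None, i:j])
        mu[b == -np.inf] = 0.0
        ll1 += _nb_loglik(y[:, i:j], mu, phi)
        i = j
    stat = np.maximum(2.0 * (ll1 - ll0), 0.0)
    p = stats.chi2.sf(stat, df=len(groups) - 1)
    p[y.sum(axis=1) == 0] = 1.0
    return pd.DataFrame(
        {"peak_id": counts.counts.index, "p_value": p, "fdr": bh_adjust(p)}
    ).set_index("peak_id")


def differential_binding(
    counts: CountMatrix,
    group_a: str,
    group_b: str,
    dispersion: str | np.ndarray = "auto",
    shrink: float = 0.3,
) -> pd.DataFrame:
    """Standard DB recipe: dispersion estimation + two-group NB LRT.

    ``dispersion='auto'`` uses the trimmed-mean common dispersion when
    either group has <= 3 replicates (moment estimates at that depth are
    too noisy for far-tail calibration), otherwise per-peak shrunk
    estimates; 'common' / 'peak' force either choice, or pass an array.
    """
    n_a = (counts.conditions == group_a).sum()
    n_b = (counts.conditions == group_b).sum()
    sub = counts.subset_samples(
        [s for s in counts.samples if counts.conditions[s] in (group_a, group_b)]
    )
    if isinstance(dispersion, str):
        if dispersion == "auto":
            dispersion = "common" if min(n_a, n_b) <= 3 else "peak"
        if dispersion == "common":
            phi = np.full(len(sub.counts), common_dispersion_mle(sub))
        elif dispersion == "peak":
            phi = estimate_dispersion(sub, shrink=shrink)
        else:
            raise ValueError("dispersion must be 'auto', 'common', 'peak' or an array")
    else:
        phi = np.asarray(dispersion, dtype=float)
    return nb_lrt_test(sub, group_a, group_b, phi)


# ---------------------------------------------------------------------- BH


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


# --------------------------------------------------------------------- PCA


def pca_peaks(counts: CountMatrix, n_components: int | None = None):
    """PCA of samples on log2 CPM (prior 0.5), peaks row-centered.

    Returns (scores DataFrame samples x PCs, variance-explained array).
    """
    if len(counts.samples) < 3:
        raise ValueError("PCA requires >= 3 samples")
    X = counts.cpm().values
    X = X - X.mean(axis=1, keepdims=True)
    if np.allclose(X, 0):
        raise ValueError("count matrix has no variance across samples")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = n_components or min(len(counts.samples), 10)
    k = min(k, len(S))
    scores = (Vt.T * S)[:, :k]
    varexp = (S**2 / np.sum(S**2))[:k]
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=counts.samples, columns=cols), varexp
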