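"""Evaluation metrics and downstream analyses for fitted models.

Covers reconstruction accuracy (per-sample KL, per-OTU MSE/Pearson),
daily-change error profiling binned by abundance percentile, ECN–taxon
correlation screening with Benjamini–Hochberg FDR control, Ward-linkage
clustering of loadings, subject-to-subject loading variability,
hypergeometric enrichment, and the Jensen–Shannon model-agreement
divergence used in sequencing-noise robustness benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom, pearsonr
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ReconstructionReport",
    "DailyChangeProfile",
    "CorrelationScreen",
    "LoadingClusters",
    "EnrichmentResult",
    "kl_reconstruction_error",
    "otu_trajectory_errors",
    "reconstruction_report",
    "daily_change_error_profile",
    "ecn_taxon_correlation_screen",
    "cluster_otus_by_loadings",
    "subject_variability_ranking",
    "hypergeometric_enrichment",
    "model_agreement_divergence",
]


def _as3d(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, float)
    return a[:, None, :] if a.ndim == 2 else a


def _default_mask(x: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    if mask is None:
        return np.ones(x.shape[1:], dtype=bool)
    m = np.asarray(mask, bool)
    return m[None, :] if m.ndim == 1 else m


# ----------------------------------------------------------------------
def kl_reconstruction_error(
    x: np.ndarray, q: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Time-normalized KL divergence between data and reconstruction.

    For each subject, sum_t sum_o x log(x / q) over observed samples,
    divided by the subject's number of observed time points (0 log 0 = 0).
    Returns one value per subject.
    """
    x, q = _as3d(x), _as3d(q)
    if x.shape != q.shape:
        raise ValueError("x and q must have matching shapes")
    if np.any(x < 0) or np.any(q <= 0):
        raise ValueError("x must be >= 0 and q strictly positive")
    m = _default_mask(x, mask)
    kl_terms = np.zeros_like(x)
    pos = (x > 0) & m[None, :, :]
    kl_terms[pos] = x[pos] * np.log(x[pos] / q[pos])
    per_sample = kl_terms.sum(axis=0)        # (S, T)
    return per_sample.sum(axis=1) / m.sum(axis=1)


def otu_trajectory_errors(
    x: np.ndarray, q: np.ndarray, mask: np.ndarray | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-OTU trajectory MSE and Pearson correlation vs reconstruction.

    Errors are computed on each OTU's longitudinal trajectory within
    each subject, then averaged over OTUs to give one number per
    subject. OTUs whose observed trajectory is constant have undefined
    correlation; they are excluded from the Pearson average and counted.

    Returns
    -------
    per_otu : DataFrame with columns (otu, subject, mse, pearson)
    per_subject : DataFrame with columns
        (subject, mean_mse, mean_pearson, n_constant_excluded)
    """
    x, q = _as3d(x), _as3d(q)
    m = _default_mask(x, mask)
    O, S, T = x.shape
    rows = []
    for s in range(S):
        ts = np.flatnonzero(m[s])
        for o in range(O):
            xo, qo = x[o, s, ts], q[o, s, ts]
            mse = float(np.mean((xo - qo) ** 2))
            if len(ts) >= 3 and np.ptp(xo) > 0 and np.ptp(qo) > 0:
                r = float(pearsonr(xo, qo)[0])
            else:
                r = np.nan
            rows.append({"otu": o, "subject": s, "mse": mse, "pearson": r})
    per_otu = pd.DataFrame(rows)
    agg = []
    for s, grp in per_otu.groupby("subject"):
        agg.append({
            "subject": s,
            "mean_mse": grp["mse"].mean(),
            "mean_pearson": grp["pearson"].mean(skipna=True),
            "n_constant_excluded": int(grp["pearson"].isna().sum()),
        })
    return per_otu, pd.DataFrame(agg)


@dataclass
class ReconstructionReport:
    """Agreement between data (or ground truth) and model reconstruction."""

    kl_per_subject: np.ndarray
    mean_kl: float
    per_otu: pd.DataFrame
    per_subject: pd.DataFrame

    def summary(self) -> str:
        ps = self.per_subject
        return (
            "Reconstruction report\n"
            f"  time-normalized KL (mean over subjects): {self.mean_kl:.6f}\n"
            f"  per-OTU MSE, subject-averaged:  {ps['mean_mse'].mean():.3e}\n"
            f"  per-OTU Pearson, subject-avg:   {ps['mean_pearson'].mean():.4f}\n"
            f"  constant OTUs excluded: {int(ps['n_constant_excluded'].sum())}"
        )


def reconstruction_report(
    x: np.ndarray, q: np.ndarray, mask: np.ndarray | None = None
) -> ReconstructionReport:
    kl = kl_reconstruction_error(x, q, mask)
    per_otu, per_subject = otu_trajectory_errors(x, q, mask)
    return ReconstructionReport(
        kl_per_subject=kl,
        mean_kl=float(np.mean(kl)),
        per_otu=per_otu,
        per_subject=per_subject,
    )


# ----------------------------------------------------------------------
@dataclass
class DailyChangeProfile:
    """Daily log10 fold-change reconstruction error, binned by abundance.

    delta = log10 x(t+1)/x(t) from the data, delta_m from the model;
    the absolute error |delta - delta_m| is binned by the abundance
    x_o(t) in intervals of 5 percentiles (20 bins).
    """

    abundance: np.ndarray       # x_o(t) for each (OTU, day) point
    abs_error: np.ndarray       # |delta - delta_m|, matched
    bin_edges: np.ndarray       # 21 percentile-based edges
    bin_mean: np.ndarray        # (20,)
    bin_sem: np.ndarray         # (20,)
    n_allzero_excluded: int
    pseudocount: float


def daily_change_error_profile(
    x: np.ndarray,
    q: np.ndarray,
    mask: np.ndarray | None = None,
    pseudocount: float | None = None,
    n_bins: int = 20,
) -> DailyChangeProfile:
    """Error in reconstructed daily abundance changes vs abundance.

    Only consecutive observed days contribute (gaps are skipped). Zeros
    are shifted by a pseudocount before the log ratio; the default is
    half the minimum nonzero relative abundance in the data. OTUs that
    are zero on every observed day are excluded and counted.
    """
    x, q = _as3d(x), _as3d(q)
    m = _default_mask(x, mask)
    if pseudocount is None:
        nz = x[(x > 0) & m[None, :, :]]
        pseudocount = float(nz.min()) / 2.0 if nz.size else 1e-6
    O, S, T = x.shape
    allzero = np.array([
        np.all(x[o][m] == 0) for o in range(O)
    ])
    abunds, errs = [], []
    for s in range(S):
        for t in range(T - 1):
            if not (m[s, t] and m[s, t + 1]):
                continue
            for o in range(O):
                if allzero[o]:
                    continue
                x0, x1 = x[o, s, t] + pseudocount, x[o, s, t + 1] + pseudocount
                q0, q1 = q[o, s, t] + pseudocount, q[o, s, t + 1] + pseudocount
                delta = np.log10(x1 / x0)
                delta_m = np.log10(q1 / q0)
                abunds.append(x[o, s, t])
                errs.append(abs(delta - delta_m))
    abunds = np.asarray(abunds)
    errs = np.asarray(errs)
    edges = np.percentile(abunds, np.linspace(0, 100, n_bins + 1))
    edges[-1] = np.nextafter(edges[-1], np.inf)
    which = np.clip(np.searchsorted(edges, abunds, side="right") - 1, 0, n_bins - 1)
    mean = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = errs[which == b]
        if sel.size:
            mean[b] = sel.mean()
            sem[b] = sel.std(ddof=1) / np.sqrt(sel.size) if sel.size > 1 else 0.0
    return DailyChangeProfile(
        abundance=abunds, abs_error=errs, bin_edges=edges,
        bin_mean=mean, bin_sem=sem,
        n_allzero_excluded=int(allzero.sum()), pseudocount=pseudocount,
    )


# ----------------------------------------------------------------------
@dataclass
class CorrelationScreen:
    """ECN–taxon correlation screen under BH FDR control."""

    table: pd.DataFrame          # (otu, subject, mode, r, p, significant)
    q_threshold: float
    per_taxon_counts: pd.Series  # significant-mode count per (otu, subject)
    frac_one: float              # fraction of taxa tied to exactly one mode
    frac_multi: float            # fraction tied to >= 2 modes

    def summary(self) -> str:
        return (
            f"ECN-taxon screen at {self.q_threshold:.0%} FDR: "
            f"{int((self.table['significant']).sum())} significant pairs; "
            f"{self.frac_one:.1%} of taxa track one mode, "
            f"{self.frac_multi:.1%} track several"
        )


def ecn_taxon_correlation_screen(
    y: np.ndarray,
    x: np.ndarray,
    mask: np.ndarray | None = None,
    q_threshold: float = 0.05,
) -> CorrelationScreen:
    """Correlate each ECN with each taxon's abundance time series.

    Pearson p-values for every (taxon, subject, mode) pair are pooled
    into a single Benjamini–Hochberg correction at ``q_threshold``. The
    fractions of taxa significantly tied to exactly one vs two-or-more
    modes summarize how mode-specific taxon dynamics are.
    """
    x = _as3d(x)
    m = _default_mask(x, mask)
    O, S, T = x.shape
    K = y.shape[1]
    rows = []
    for s in range(S):
        ts = np.flatnonzero(m[s])
        if len(ts) < 3:
            raise ValueError("need at least 3 observed time points per subject")
        for o in range(O):
            xo = x[o, s, ts]
            for k in range(K):
                yk = y[ts, k]
                if np.ptp(xo) == 0 or np.ptp(yk) == 0:
                    r, p = 0.0, 1.0
                else:
                    r, p = pearsonr(xo, yk)
                rows.append({"otu": o, "subject": s, "mode": k + 1,
                             "r": float(r), "p": float(p)})
    tab = pd.DataFrame(rows)
    tab["significant"] = multipletests(
        tab["p"].to_numpy(), alpha=q_threshold, method="fdr_bh"
    )[0]
    counts = tab.groupby(["otu", "subject"])["significant"].sum()
    frac_one = float((counts == 1).mean())
    frac_multi = float((counts >= 2).mean())
    return CorrelationScreen(
        table=tab, q_threshold=q_threshold, per_taxon_counts=counts,
        frac_one=frac_one, frac_multi=frac_multi,
    )


# ----------------------------------------------------------------------
@dataclass
class LoadingClusters:
    """Ward-linkage clustering of OTUs in loading space."""

    components: list[int]          # 1-based mode numbers used
    features: np.ndarray           # (O, n_features)
    linkage_matrix: np.ndarray     # scipy linkage output
    labels: np.ndarray | None      # cluster labels at the requested cut
    otu_ids: list | None = None

    def to_newick(self) -> str:
        """Serialize the dendrogram as a Newick string."""
        n = self.features.shape[0]
        names = (
            [str(i) for i in self.otu_ids]
            if self.otu_ids is not None
            else [f"otu{i}" for i in range(n)]
        )

        def node(i: int, parent_h: float) -> str:
            if i < n:
                return f"{names[i]}:{parent_h:.6g}"
            a, b, h, _ = self.linkage_matrix[i - n]
            return (
                f"({node(int(a), h)},{node(int(b), h)}):"
                f"{max(parent_h - h, 0.0):.6g}"
            )

        root_h = self.linkage_matrix[-1, 2] if len(self.linkage_matrix) else 0.0
        return node(n + len(self.linkage_matrix) - 1, root_h) + ";"


def cluster_otus_by_loadings(
    phi: np.ndarray,
    component_subset: list[int],
    subject_mode: str = "concat",
    n_clusters: int | None = None,
    cut_height: float | None = None,
    otu_ids: list | None = None,
) -> LoadingClusters:
    """Hierarchically cluster OTUs by their loadings on selected modes.

    ``phi`` is (K, O, S); ``component_subset`` lists 1-based mode
    numbers (e.g. [2, 3] to cluster on the oscillatory modes while
    ignoring the mean-abundance mode 1). Subjects are either
    concatenated into one feature vector per OTU (``"concat"``) or
    averaged (``"mean"``). Ward's linkage; labels are returned at the
    requested cut (``n_clusters`` or ``cut_height``), else no cut.
    """
    phi = np.asarray(phi, float)
    K, O, S = phi.shape
    comps = sorted(set(int(c) for c in component_subset))
    if not comps:
        raise ValueError("component_subset must be non-empty")
    if any(c < 1 or c > K for c in comps):
        raise ValueError(f"mode numbers must lie in 1..{K}")
    idx = [c - 1 for c in comps]
    if subject_mode == "concat":
        feats = phi[idx].transpose(1, 0, 2).reshape(O, -1)
    elif subject_mode == "mean":
        feats = phi[idx].mean(axis=2).T
    else:
        raise ValueError("subject_mode must be 'concat' or 'mean'")
    if n_clusters is not None and n_clusters > O:
        raise ValueError("more clusters requested than OTUs")
    Z = linkage(feats, method="ward")
    labels = None
    if n_clusters is not None:
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    elif cut_height is not None:
        labels = fcluster(Z, t=cut_height, criterion="distance")
    return LoadingClusters(
        components=comps, features=feats, linkage_matrix=Z,
        labels=labels, otu_ids=otu_ids,
    )


def subject_variability_ranking(
    phi: np.ndarray, otu_ids: list | None = None
) -> pd.Series:
    """Average pairwise between-subject distance of each OTU's loadings.

    Each OTU carries one K-vector of loadings per subject; the mean
    Euclidean distance over all subject pairs is small for OTUs with
    universal dynamics and large for subject-specific ones. Returned
    sorted ascending (most universal first).
    """
    phi = np.asarray(phi, float)
    K, O, S = phi.shape
    if S < 2:
        raise ValueError("need at least 2 subjects")
    vecs = phi.transpose(1, 2, 0)  # (O, S, K)
    dists = np.zeros(O)
    n_pairs = S * (S - 1) // 2
    for i in range(S):
        for j in range(i + 1, S):
            dists += np.linalg.norm(vecs[:, i] - vecs[:, j], axis=1)
    dists /= n_pairs
    index = otu_ids if otu_ids is not None else list(range(O))
    return pd.Series(dists, index=index, name="mean_pairwise_distance").sort_values()


# ----------------------------------------------------------------------
@dataclass
class EnrichmentResult:
    """Upper-tail hypergeometric enrichment of a category in a cluster."""

    k: int       # observed successes in the sample
    n: int       # sample size (e.g. cluster size)
    K_pop: int   # successes in the population (e.g. genus members)
    N_pop: int   # population size
    p_value: float

    def summary(self) -> str:
        return (
            f"{self.k}/{self.n} vs {self.K_pop}/{self.N_pop}: "
            f"hypergeometric p = {self.p_value:.2g}"
        )


def hypergeometric_enrichment(
    k: int, n: int, K_pop: int, N_pop: int
) -> EnrichmentResult:
    """P(X >= k) for X ~ Hypergeometric(N_pop, K_pop, n), exact tail."""
    if not (0 <= k <= min(n, K_pop) and n <= N_pop and K_pop <= N_pop):
        raise ValueError(
            f"inconsistent counts: k={k}, n={n}, K_pop={K_pop}, N_pop={N_pop}"
        )
    p = float(hypergeom.sf(k - 1, N_pop, K_pop, n))
    return EnrichmentResult(k=k, n=n, K_pop=K_pop, N_pop=N_pop, p_value=p)


# ----------------------------------------------------------------------
def model_agreement_divergence(
    q1: np.ndarray, q2: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Jensen–Shannon divergence between two models' compositions.

    JSD(p, q) = H(m) - (H(p) + H(q))/2 with m the equal mixture, in bits
    (base 2), computed per sample and averaged over observed samples.
    Symmetric in its arguments; 0 iff the models agree; at most 1 bit.
    """
    q1, q2 = _as3d(q1), _as3d(q2)
    if q1.shape != q2.shape:
        raise ValueError("propensity tensors must have matching shapes")
    m = _default_mask(q1, mask)
    for q in (q1, q2):
        sums = q.sum(axis=0)[m]
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("propensity columns must sum to 1")

    def ent(p: np.ndarray) -> np.ndarray:
        terms = np.where(p > 0, -p * np.log2(np.maximum(p, 1e-300)), 0.0)
        return terms.sum(axis=0)  # (S, T)

    mix = 0.5 * (q1 + q2)
    jsd = ent(mix) - 0.5 * (ent(q1) + ent(q2))
    return float(jsd[m].mean())
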