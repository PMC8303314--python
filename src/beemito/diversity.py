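"""Per-site diversity statistics, AMOVA-based PhiPT and PCoA.

Statistics follow the single-locus haploid definitions used for mtDNA
haplotype data: with haplotype frequencies p_i in a site of N colonies,

* ``Na``  number of distinct haplotypes observed,
* ``Ne``  effective number of haplotypes, 1 / sum(p_i^2),
* ``Np``  private haplotypes (observed in that site and nowhere else),
* ``uh``  unbiased haplotype diversity, (N/(N-1)) * (1 - sum(p_i^2)).

PhiPT is the AMOVA analogue of FST for categorical (haplotypic) data: the
among-site fraction of total molecular variance computed from squared
pairwise distances with the binary metric d(i,j) = 0 if both colonies carry
the same label and 1 otherwise.  Significance is assessed by permuting
colonies among sites.  PCoA is classical metric ordination (Gower
double-centering of -D^2/2 followed by eigendecomposition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DiversitySummary:
    site: str
    n: int
    na: int
    np_private: int
    ne: float
    uh: float | None    # undefined (None) when N < 2

    def validate(self) -> None:
        if not (1 <= self.ne + 1e-9 and self.ne <= self.na + 1e-9
                and self.na <= self.n):
            raise ValueError(f"{self.site}: Ne/Na/N ordering violated")
        if self.np_private > self.na:
            raise ValueError(f"{self.site}: Np exceeds Na")
        if self.uh is not None and not -1e-12 <= self.uh <= 1.0 + 1e-12:
            raise ValueError(f"{self.site}: uh outside [0, 1]")


@dataclass
class PhiPTResult:
    phi_pt: float                  # clamped to [0, 1] for reporting
    phi_pt_raw: float              # unclamped estimate (may be negative)
    sigma_among: float
    sigma_within: float
    p_value: float | None
    pairwise: pd.DataFrame         # clamped pairwise PhiPT between sites
    pairwise_raw: pd.DataFrame
    pairwise_p: pd.DataFrame | None


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame      # sites x axes
    eigenvalues: np.ndarray        # all eigenvalues, descending
    percent_variance: np.ndarray   # per positive axis, sums to 100
    negative_eigenvalues: np.ndarray


# ---------------------------------------------------------------------------
# Per-site summaries
# ---------------------------------------------------------------------------

def unbiased_diversity(counts) -> float:
    """uh = (N/(N-1)) * (1 - sum p_i^2) for one site's haplotype counts."""
    c = np.asarray(list(counts), dtype=float)
    n = c.sum()
    if n < 2:
        raise ValueError("uh requires at least two individuals")
    sum_p2 = float(np.sum((c / n) ** 2))
    return (n / (n - 1.0)) * (1.0 - sum_p2)


def uh_from_n_and_ne(n: int, ne: float) -> float:
    """Algebraic identity uh = (N/(N-1)) * (1 - 1/Ne)."""
    return (n / (n - 1.0)) * (1.0 - 1.0 / ne)


def diversity_summary(pop: pd.DataFrame) -> list[DiversitySummary]:
    """Per-site diversity parameters from a site x haplotype count table.

    ``pop`` is a long-format DataFrame with columns site, haplotype, count
    (as produced by :func:`population_table`).  Np counts site-private
    haplotypes.  uh is reported as None for sites with N < 2.
    """
    if not {"site", "haplotype", "count"} <= set(pop.columns):
        raise ValueError("population table needs site/haplotype/count columns")
    pop = pop[pop["count"] > 0]
    sites_per_hap = pop.groupby("haplotype")["site"].nunique()
    private_haps = set(sites_per_hap[sites_per_hap == 1].index)
    out = []
    for site, sub in pop.groupby("site", sort=False):
        counts = sub.set_index("haplotype")["count"]
        n = int(counts.sum())
        na = int((counts > 0).sum())
        ne = 1.0 / float(np.sum((counts / n) ** 2))
        np_priv = int(sum(h in private_haps for h in counts.index))
        uh = unbiased_diversity(counts) if n >= 2 else None
        summary = DiversitySummary(site=site, n=n, na=na, np_private=np_priv,
                                   ne=ne, uh=uh)
        summary.validate()
        out.append(summary)
    return out


def summaries_to_frame(summaries, site_regions=None, decimals: int = 3
                       ) -> pd.DataFrame:
    """Report-layer table (Ne and uh rounded to ``decimals``)."""
    df = pd.DataFrame([{
        "site": s.site, "N": s.n, "Na": s.na, "Np": s.np_private,
        "Ne": round(s.ne, decimals),
        "uh": None if s.uh is None else round(s.uh, decimals),
    } for s in summaries])
    if site_regions is not None:
        df.insert(0, "region", df["site"].map(site_regions))
    return df


def population_table(typing_df: pd.DataFrame) -> pd.DataFrame:
    """Site x haplotype counts (long format) from a typing table."""
    counts = (typing_df.groupby(["site", "haplotype"], sort=False)
              .size().reset_index(name="count"))
    return counts


# ---------------------------------------------------------------------------
# PhiPT (AMOVA on binary label distances)
# ---------------------------------------------------------------------------

def _amova_binary(labels: np.ndarray, sites: np.ndarray,
                  site_ids: np.ndarray) -> tuple[float, float, float]:
    """Variance components for binary-distance AMOVA.

    Returns (sigma2_among, sigma2_within, phi_pt_raw).  Uses the closed-form
    sums of squares: for binary distances the sum of squared distances within
    a group of size n with label counts c_h is (n^2 - sum c_h^2) / 2, and
    SS = that / n.
    """
    n_total = labels.size
    k = site_ids.size
    uniq_labels, lab_codes = np.unique(labels, return_inverse=True)
    ss_within = 0.0
    sum_n2 = 0.0
    for sid in site_ids:
        mask = sites == sid
        n_p = int(mask.sum())
        counts = np.bincount(lab_codes[mask], minlength=uniq_labels.size)
        ss_within += (n_p * n_p - float(np.sum(counts ** 2))) / (2.0 * n_p)
        sum_n2 += n_p * n_p
    total_counts = np.bincount(lab_codes, minlength=uniq_labels.size)
    ss_total = (n_total * n_total - float(np.sum(total_counts ** 2))) / (2.0 * n_total)
    ss_among = ss_total - ss_within

    df_among = k - 1
    df_within = n_total - k
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    n0 = (n_total - sum_n2 / n_total) / df_among
    sigma_among = (ms_among - ms_within) / n0
    sigma_within = ms_within
    denom = sigma_among + sigma_within
    phi = sigma_among / denom if denom > 0 else 0.0
    return sigma_among, sigma_within, phi


def phi_pt(assignments, sites, n_permutations: int = 999,
           seed: int | None = None, compute_pairwise: bool = True
           ) -> PhiPTResult:
    """PhiPT differentiation among sampling sites from per-colony labels.

    ``assignments`` and ``sites`` are equal-length sequences giving each
    colony's categorical label (lineage, sub-lineage or haplotype) and its
    sampling site.  Sites with fewer than two colonies are excluded with a
    warning.  Permutation p-values (colonies shuffled among sites) are
    computed when ``n_permutations`` > 0, which then requires a seed.
    """
    labels = np.asarray(list(assignments))
    site_arr = np.asarray(list(sites))
    if labels.size != site_arr.size:
        raise ValueError("assignments and sites differ in length")
    uniq_sites, counts = np.unique(site_arr, return_counts=True)
    small = uniq_sites[counts < 2]
    if small.size:
        warnings.warn(f"excluding sites with a single colony: {list(small)}")
        keep = ~np.isin(site_arr, small)
        labels, site_arr = labels[keep], site_arr[keep]
        uniq_sites = uniq_sites[counts >= 2]
    if uniq_sites.size < 2:
        raise ValueError("PhiPT requires at least two sites with >=2 colonies")
    if n_permutations > 0 and seed is None:
        raise ValueError("a seed is required when permuting")
    rng = np.random.default_rng(seed) if n_permutations > 0 else None

    def run(lab, st, ids):
        return _amova_binary(lab, st, ids)

    def perm_p(lab, st, ids, observed_phi):
        if n_permutations <= 0:
            return None
        exceed = 0
        lab_work = lab.copy()
        for _ in range(n_permutations):
            rng.shuffle(lab_work)
            _, _, phi = run(lab_work, st, ids)
            if phi >= observed_phi - 1e-12:
                exceed += 1
        return (exceed + 1.0) / (n_permutations + 1.0)

    sa, sw, phi_raw = run(labels, site_arr, uniq_sites)
    p_global = perm_p(labels, site_arr, uniq_sites, phi_raw)

    k = uniq_sites.size
    raw = np.zeros((k, k))
    clamped = np.zeros((k, k))
    pvals = (np.full((k, k), np.nan)
             if n_permutations > 0 and compute_pairwise else None)
    for i in range(k if compute_pairwise else 0):
        for j in range(i + 1, k):
            mask = np.isin(site_arr, [uniq_sites[i], uniq_sites[j]])
            lab_ij, st_ij = labels[mask], site_arr[mask]
            ids_ij = uniq_sites[[i, j]]
            _, _, pij = run(lab_ij, st_ij, ids_ij)
            raw[i, j] = raw[j, i] = pij
            clamped[i, j] = clamped[j, i] = max(0.0, pij)
            if pvals is not None:
                pvals[i, j] = pvals[j, i] = perm_p(lab_ij, st_ij, ids_ij, pij)
    idx = list(uniq_sites)
    return PhiPTResult(
        phi_pt=max(0.0, phi_raw), phi_pt_raw=phi_raw,
        sigma_among=sa, sigma_within=sw, p_value=p_global,
        pairwise=pd.DataFrame(clamped, index=idx, columns=idx),
        pairwise_raw=pd.DataFrame(raw, index=idx, columns=idx),
        pairwise_p=None if pvals is None else pd.DataFrame(pvals, index=idx,
                                                           columns=idx))


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def pcoa(distance: pd.DataFrame | np.ndarray, labels=None) -> PCoAResult:
    """Principal coordinate analysis of a symmetric distance matrix.

    Gower double-centering of -D^2/2 followed by eigendecomposition; axes are
    ordered by decreasing eigenvalue, per-axis percent variance uses only the
    positive eigenvalues (which therefore sum to 100); negative eigenvalues
    are excluded from the denominator and reported separately.
    """
    if isinstance(distance, pd.DataFrame):
        labels = list(distance.index)
        d = distance.to_numpy(dtype=float)
    else:
        d = np.asarray(distance, dtype=float)
        labels = list(labels) if labels is not None else list(range(len(d)))
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")

    n = d.shape[0]
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(1e-12, 1e-10 * max(1.0, float(np.abs(eigvals).max(initial=0.0))))
    pos = eigvals > tol
    neg = eigvals < -tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pos_sum = eigvals[pos].sum()
    percent = (eigvals[pos] / pos_sum * 100.0) if pos_sum > 0 else np.array([])
    coord_df = pd.DataFrame(coords, index=labels,
                            columns=[f"axis{i+1}" for i in range(coords.shape[1])])
    return PCoAResult(coordinates=coord_df, eigenvalues=eigvals,
                      percent_variance=percent,
                      negative_eigenvalues=eigvals[neg])
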