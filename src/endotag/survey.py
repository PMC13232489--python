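"""Tagged-allele inventory curation and survey statistics.

Covers the curation rules applied to a literature + stock-center inventory of
endogenously tagged alleles (one representative allele per identical design,
earliest publication kept), the summary distributions (alleles per gene, tag
types, tag positions), accrual models (linear tagging rate, exponential-
saturation discovery curve), and per-category enrichment of tagged genes:
odds ratio from a 2x2 table, two-sided Fisher exact p, Benjamini-Hochberg
FDR, and log2(OR) with +/-7 substituted for infinite values so fully tagged
or untagged categories stay plottable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

TAG_POSITIONS = ("N", "C", "internal")


@dataclass(frozen=True)
class AlleleRecord:
    gene_id: str
    gene_name: str
    tags: frozenset
    tag_positions: frozenset
    source: str  # 'literature' | 'CGC'
    allele_designation: str | None = None
    year: int | None = None
    reference_id: str | None = None

    def __post_init__(self):
        if not self.tags:
            raise ValueError(f"{self.gene_id}: allele must carry at least one tag")
        bad = set(self.tag_positions) - set(TAG_POSITIONS)
        if bad:
            raise ValueError(f"{self.gene_id}: unknown tag positions {sorted(bad)}")
        if self.year is not None and not (1990 <= self.year <= 2100):
            raise ValueError(f"{self.gene_id}: implausible year {self.year}")


def read_inventory(path) -> tuple[list[AlleleRecord], int]:
    """Read the inventory TSV; malformed rows are skipped and counted.

    Columns: gene_id, gene_name, allele, tags (';'-separated), positions,
    source, year, reference.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    records, skipped = [], 0
    for row in df.itertuples(index=False):
        try:
            records.append(
                AlleleRecord(
                    gene_id=row.gene_id,
                    gene_name=row.gene_name,
                    allele_designation=row.allele or None,
                    tags=frozenset(t for t in row.tags.split(";") if t),
                    tag_positions=frozenset(p for p in row.positions.split(";") if p),
                    source=row.source,
                    year=int(row.year) if row.year else None,
                    reference_id=row.reference or None,
                )
            )
        except (ValueError, AttributeError):
            skipped += 1
    return records, skipped


# ---------------------------------------------------------------------------
# Curation


def _dedup_key(r: AlleleRecord):
    return (r.gene_id, tuple(sorted(r.tags)), tuple(sorted(r.tag_positions)))


def dedup_alleles(records: list[AlleleRecord]) -> list[AlleleRecord]:
    """One representative allele per (gene, tags, positions): the earliest
    publication wins; ties break on lexicographic allele designation."""
    groups: dict[tuple, AlleleRecord] = {}
    for r in records:
        key = _dedup_key(r)
        cur = groups.get(key)
        if cur is None:
            groups[key] = r
            continue
        rank = (r.year if r.year is not None else math.inf, r.allele_designation or "~")
        cur_rank = (
            cur.year if cur.year is not None else math.inf,
            cur.allele_designation or "~",
        )
        if rank < cur_rank:
            groups[key] = r
    return list(groups.values())


def merge_sources(
    literature: list[AlleleRecord], cgc: list[AlleleRecord]
) -> tuple[pd.DataFrame, dict]:
    """Merge literature and stock-center records; classify every allele and
    gene as literature_only / cgc_only / both.

    Alleles join on the allele designation when present, else on
    (gene, tags, positions). Conflicting gene assignments for one designation
    warn and keep the literature gene.
    """
    def join_key(r: AlleleRecord):
        if r.allele_designation:
            return ("designation", r.allele_designation)
        return ("fallback",) + _dedup_key(r)

    rows = []
    lit_by_key = {}
    warnings = []
    for r in literature:
        lit_by_key[join_key(r)] = r
    cgc_by_key = {}
    for r in cgc:
        key = join_key(r)
        cgc_by_key[key] = r
        lit = lit_by_key.get(key)
        if lit is not None and lit.gene_id != r.gene_id:
            warnings.append(
                f"designation {r.allele_designation}: gene conflict "
                f"{lit.gene_id} (literature) vs {r.gene_id} (CGC); literature kept"
            )
    for key, r in lit_by_key.items():
        cls = "both" if key in cgc_by_key else "literature_only"
        rows.append((r.gene_id, r.allele_designation, cls))
    for key, r in cgc_by_key.items():
        if key not in lit_by_key:
            rows.append((r.gene_id, r.allele_designation, "cgc_only"))
    merged = pd.DataFrame(rows, columns=["gene_id", "allele", "source_class"])
    gene_class = {}
    for gid, grp in merged.groupby("gene_id"):
        classes = set(grp["source_class"])
        if classes == {"cgc_only"}:
            gene_class[gid] = "cgc_only"
        elif "both" in classes or ({"literature_only", "cgc_only"} <= classes):
            gene_class[gid] = "both"
        else:
            gene_class[gid] = "literature_only"
    allele_counts = merged["source_class"].value_counts().to_dict()
    gene_counts = pd.Series(gene_class).value_counts().to_dict()
    summary = {
        "alleles": {k: allele_counts.get(k, 0) for k in ("literature_only", "cgc_only", "both")},
        "genes": {k: gene_counts.get(k, 0) for k in ("literature_only", "cgc_only", "both")},
        "warnings": warnings,
    }
    return merged, summary


# ---------------------------------------------------------------------------
# Summary distributions


def round_half_away(x: float, decimals: int = 1) -> float:
    scale = 10**decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def category_proportion(t: int, n: int, decimals: int = 1) -> float:
    """Percentage of tagged genes in a category, rounded half away from zero."""
    if n <= 0:
        raise ValueError("category size must be positive")
    if not (0 <= t <= n):
        raise ValueError(f"tagged count {t} outside [0, {n}]")
    return round_half_away(100.0 * t / n, decimals)


@dataclass
class InventorySummary:
    n_genes: int
    n_alleles: int
    alleles_per_gene_pct: dict  # {'1','2','3','4+'} -> % of genes
    tag_type_pct: dict  # % of tag instances per tag name (sums to 100)
    tag_of_allele_pct: dict  # % of alleles carrying each tag (overlapping)
    position_pct: dict  # {'N','C','internal','multiple'} -> % of alleles


def summarize_inventory(records: list[AlleleRecord]) -> InventorySummary:
    """Fig-1-style distributions of a deduplicated inventory. An allele with
    tags at more than one position counts once under 'multiple'."""
    if not records:
        return InventorySummary(0, 0, {}, {}, {}, {})
    n_alleles = len(records)
    per_gene: dict[str, int] = {}
    for r in records:
        per_gene[r.gene_id] = per_gene.get(r.gene_id, 0) + 1
    n_genes = len(per_gene)
    buckets = {"1": 0, "2": 0, "3": 0, "4+": 0}
    for c in per_gene.values():
        buckets[str(c) if c < 4 else "4+"] += 1
    apg = {k: 100.0 * v / n_genes for k, v in buckets.items()}

    tag_instances: dict[str, int] = {}
    allele_with_tag: dict[str, int] = {}
    for r in records:
        for t in r.tags:
            tag_instances[t] = tag_instances.get(t, 0) + 1
            allele_with_tag[t] = allele_with_tag.get(t, 0) + 1
    total_instances = sum(tag_instances.values())
    tag_pct = {t: 100.0 * v / total_instances for t, v in sorted(tag_instances.items())}
    tag_allele_pct = {
        t: 100.0 * v / n_alleles for t, v in sorted(allele_with_tag.items())
    }

    pos_counts = {"N": 0, "C": 0, "internal": 0, "multiple": 0}
    for r in records:
        if len(r.tag_positions) > 1:
            pos_counts["multiple"] += 1
        else:
            (pos,) = r.tag_positions
            pos_counts[pos] += 1
    pos_pct = {k: 100.0 * v / n_alleles for k, v in pos_counts.items()}
    return InventorySummary(n_genes, n_alleles, apg, tag_pct, tag_allele_pct, pos_pct)


# ---------------------------------------------------------------------------
# Enrichment

LOG2_OR_CAP = 7.0


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    tagged_in_category: int
    category_size: int
    background_tagged: int
    background_size: int
    proportion: float
    odds_ratio: float
    log2_or_capped: float
    p_value: float
    q_value: float = float("nan")
    significant: bool = False


def _capped_log2_or(odds_ratio: float) -> float:
    if math.isnan(odds_ratio):
        return float("nan")
    if odds_ratio == 0.0:
        return -LOG2_OR_CAP
    if math.isinf(odds_ratio):
        return LOG2_OR_CAP
    return math.log2(odds_ratio)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR q-values: q_i = min_{j >= rank(i)} p_(j)*m/j, clipped to 1,
    returned in the original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def enrichment_table(
    category_counts, background_tagged: int, background_size: int, fdr: float = 0.05
) -> pd.DataFrame:
    """Per-category enrichment of tagged genes against the background.

    ``category_counts`` is an iterable of (term_id, term_name, t, n) with
    ``t`` tagged genes among the ``n`` genes of the category; background is
    (T tagged, N total). The 2x2 table is
    [[t, n-t], [T-t, (N-n)-(T-t)]], OR its cross-product ratio, p a two-sided
    Fisher exact test, q Benjamini-Hochberg across all categories.
    """
    T, N = background_tagged, background_size
    results: list[EnrichmentResult] = []
    for term_id, term_name, t, n in category_counts:
        cells = (t, n - t, T - t, (N - n) - (T - t))
        if any(c < 0 for c in cells):
            raise ValueError(
                f"{term_id}: negative cell in 2x2 table {cells} "
                f"(t={t}, n={n}, T={T}, N={N})"
            )
        a, b, c, d = cells
        num, den = a * d, b * c
        if den > 0:
            odds = num / den
        elif num > 0:
            odds = math.inf
        else:
            odds = math.nan  # degenerate 0/0 table
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        results.append(
            EnrichmentResult(
                term_id=term_id,
                term_name=term_name,
                tagged_in_category=t,
                category_size=n,
                background_tagged=T,
                background_size=N,
                proportion=category_proportion(t, n),
                odds_ratio=odds,
                log2_or_capped=_capped_log2_or(odds),
                p_value=float(p),
            )
        )
    q = benjamini_hochberg([r.p_value for r in results])
    for r, qi in zip(results, q):
        r.q_value = float(qi)
        r.significant = bool(qi < fdr)
    return pd.DataFrame([vars(r) for r in results])


def read_categories(path) -> pd.DataFrame:
    """Category-annotation TSV: term_id, term_name, ontology, gene_id."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")


def enrichment_from_annotations(
    tagged_genes: set,
    categories: pd.DataFrame,
    background_genes: set,
    fdr: float = 0.05,
    min_category_size: int = 1,
) -> pd.DataFrame:
    """Build per-term counts from a term->gene annotation table and run
    enrichment_table against the supplied background gene universe."""
    tagged = tagged_genes & background_genes
    counts = []
    for (term_id, term_name), grp in categories.groupby(["term_id", "term_name"]):
        genes = set(grp["gene_id"]) & background_genes
        if len(genes) < min_category_size:
            continue
        counts.append((term_id, term_name, len(genes & tagged), len(genes)))
    return enrichment_table(counts, len(tagged), len(background_genes), fdr=fdr)


# ---------------------------------------------------------------------------
# Accrual models


def cumulative_accrual(records: list[AlleleRecord]) -> pd.Series:
    """Cumulative number of unique tagged genes per year; a gene counts once,
    in its earliest year."""
    first_year: dict[str, int] = {}
    for r in records:
        if r.year is None:
            continue
        cur = first_year.get(r.gene_id)
        if cur is None or r.year < cur:
            first_year[r.gene_id] = r.year
    if not first_year:
        return pd.Series(dtype=int)
    counts = pd.Series(first_year).value_counts().sort_index()
    years = range(int(counts.index.min()), int(counts.index.max()) + 1)
    per_year = counts.reindex(years, fill_value=0)
    return per_year.cumsum()


def linear_fit(
    cumulative: pd.Series, year_min: int | None = None, year_max: int | None = None
) -> tuple[float, float, float]:
    """OLS fit of cumulative tagged genes vs year -> (slope, intercept, R^2)."""
    s = cumulative
    if year_min is not None:
        s = s[s.index >= year_min]
    if year_max is not None:
        s = s[s.index <= year_max]
    if s.index.nunique() < 2:
        raise ValueError("need at least two distinct years for a linear fit")
    res = stats.linregress(s.index.to_numpy(float), s.to_numpy(float))
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


@dataclass
class AccrualFit:
    model: str  # 'linear' | 'exponential_saturation'
    parameters: dict
    r_squared: float
    converged: bool = True

    def papers_for_fraction(self, fraction: float) -> float:
        """Sampling effort at which the saturating model reaches the given
        fraction of its asymptote: n = -tau * ln(1 - f)."""
        if self.model != "exponential_saturation":
            raise ValueError("papers_for_fraction requires the saturation model")
        if not (0 < fraction < 1):
            raise ValueError("fraction must be in (0, 1)")
        return -self.parameters["tau"] * math.log(1.0 - fraction)


def discovery_curve_fit(papers, cumulative_new_genes) -> AccrualFit:
    """Least-squares fit of G(n) = G_max * (1 - exp(-n / tau)) to a monotone
    cumulative discovery series."""
    x = np.asarray(papers, dtype=float)
    y = np.asarray(cumulative_new_genes, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least three points")
    if (np.diff(y) < 0).any():
        raise ValueError("cumulative series must be non-decreasing")
    g0 = max(y.max(), 1.0) * 1.2
    tau0 = max(x.max() / 3.0, 1.0)

    def model(n, g_max, tau):
        return g_max * (1.0 - np.exp(-n / tau))

    try:
        popt, _ = optimize.curve_fit(
            model, x, y, p0=(g0, tau0), bounds=([1e-9, 1e-9], [np.inf, np.inf]),
            maxfev=10000,
        )
        converged = True
    except RuntimeError:
        return AccrualFit(
            "exponential_saturation", {"g_max": float("nan"), "tau": float("nan")},
            float("nan"), converged=False,
        )
    resid = y - model(x, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return AccrualFit(
        "exponential_saturation",
        {"g_max": float(popt[0]), "tau": float(popt[1])},
        r2,
        converged=converged,
    )
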