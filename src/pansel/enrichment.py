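"""COG-category enrichment of positively selected genes.

For every functional category, the number of selected genes annotated to it
is tested against the category's share of the core-genome background with a
one-sided (upper-tail) exact binomial test: small p means the category is
over-represented among selected genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy.stats import binom

#: the standard single-letter COG functional categories
COG_CATEGORIES = set("JAKLBDYVTMNZWUOXCGEFHIPQRS")
UNCATEGORIZED = "uncategorized"


@dataclass
class CogMap:
    """gene/family id -> one or more COG category letters."""

    assignments: dict[str, str]

    def categories_of(self, gene: str) -> list[str]:
        cats = self.assignments.get(gene, "")
        return list(cats) if cats else [UNCATEGORIZED]


def load_cog_map(path) -> CogMap:
    """Read a two-column TSV of gene id and category letter(s).

    Unknown letters are warned about and bucketed as uncategorized; a gene
    annotated ``JK`` contributes to both J and K.
    """
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {line_no}: expected 2 tab-separated columns")
            gene, cats = parts
            if line_no == 1 and cats.lower() in ("cog", "category", "categories"):
                continue
            good = "".join(c for c in cats.upper() if c in COG_CATEGORIES)
            if len(good) != len(cats):
                warnings.warn(f"line {line_no}: unknown COG letter(s) in {cats!r}; "
                              "gene treated as uncategorized where unmapped")
            assignments[gene] = good
    return CogMap(assignments)


def save_cog_map(cogmap: CogMap, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(cogmap.assignments):
            fh.write(f"{gene}\t{cogmap.assignments[gene]}\n")


def binomial_enrichment(k: int, n: int, p0: float) -> float:
    """Exact upper-tail P(X >= k) for X ~ Binomial(n, p0)."""
    if not 0 <= p0 <= 1:
        raise ValueError("background proportion p0 must lie in [0, 1]")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if k == 0:
        return 1.0
    return float(binom.sf(k - 1, n, p0))


@dataclass
class EnrichmentRow:
    category: str
    k_selected: int
    n_selected: int
    k_core: int
    n_core: int
    proportion_selected: float
    proportion_core: float
    p_value: float


def _category_counts(genes: set[str], cogmap: CogMap) -> dict[str, int]:
    counts: dict[str, int] = {}
    for gene in genes:
        for cat in cogmap.categories_of(gene):
            counts[cat] = counts.get(cat, 0) + 1
    return counts


def enrichment_table(selected: set[str], background: set[str], cogmap: CogMap
                     ) -> list[EnrichmentRow]:
    """Per-category one-sided binomial enrichment of ``selected`` within
    ``background``; rows sorted by ascending p-value.

    A multi-category gene counts once in each of its categories; the
    background proportion of a category is its count over the background
    size.
    """
    if not background:
        raise ValueError("empty background gene set")
    extra = selected - background
    if extra:
        raise ValueError(f"selected genes missing from background: {sorted(extra)[:5]}")
    sel_counts = _category_counts(selected, cogmap)
    core_counts = _category_counts(background, cogmap)
    n_sel, n_core = len(selected), len(background)
    rows = []
    for cat in sorted(core_counts):
        k_sel = sel_counts.get(cat, 0)
        k_core = core_counts[cat]
        p0 = k_core / n_core
        rows.append(EnrichmentRow(
            cat, k_sel, n_sel, k_core, n_core,
            k_sel / n_sel if n_sel else 0.0, p0,
            binomial_enrichment(k_sel, n_sel, p0) if n_sel else 1.0))
    rows.sort(key=lambda r: (r.p_value, r.category))
    return rows


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """BH-adjusted q-values, order preserved (optional; raw p is the default)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top, idx in enumerate(reversed(order)):
        rank = m - rank_from_top
        prev = min(prev, p_values[idx] * m / rank)
        q[idx] = prev
    return q


def write_enrichment_tsv(rows: list[EnrichmentRow], path) -> None:
    cols = ["category", "k_selected", "n_selected", "k_core", "n_core",
            "proportion_selected", "proportion_core", "p_value"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write(f"{r.category}\t{r.k_selected}\t{r.n_selected}\t{r.k_core}\t"
                     f"{r.n_core}\t{r.proportion_selected:.6f}\t"
                     f"{r.proportion_core:.6f}\t{r.p_value:.6g}\n")
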