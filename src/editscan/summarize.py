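"""Summary surfaces over detected candidates.

Covers the four report tables: per-tissue 12-type mismatch counts (all
sites vs those inside repetitive elements), cross-tissue sharing on
(chrom, pos, strand), repeat family/element distributions and genic
location-category distributions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Union

import pandas as pd

from .types import (
    AnnotatedCandidate,
    EditCandidate,
    LOCATION_CATEGORIES,
    MISMATCH_TYPES,
)

Candidate = Union[EditCandidate, AnnotatedCandidate]


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """Share of total as a percentage, round-half-even to ``ndigits``."""
    if total == 0:
        return 0.0
    return round(100.0 * count / total, ndigits)


def _has_repeat(c: Candidate) -> bool:
    return isinstance(c, AnnotatedCandidate) and c.repeat is not None


@dataclass
class MismatchSummary:
    """Counts per (tissue, mismatch type) with per-type shares of the scope total."""

    scope: str  # "all" or "repetitive"
    counts: dict[tuple[str, str], int]
    total: int
    percentages: dict[str, float]  # per type, over the scope total

    def type_total(self, mismatch_type: str) -> int:
        return sum(
            n for (_, t), n in self.counts.items() if t == mismatch_type
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"tissue": tissue, "type": t, "count": n}
            for (tissue, t), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["tissue", "type", "count"])


def summarize_types(
    candidates: Iterable[Candidate], scope: str = "all"
) -> MismatchSummary:
    """Count candidates per (tissue, type); percentages over the scope total.

    ``scope='repetitive'`` restricts to candidates annotated with a
    containing repeat interval.  Each candidate is one per-tissue event and
    is counted exactly once.
    """
    if scope not in ("all", "repetitive"):
        raise ValueError(f"scope must be 'all' or 'repetitive', got {scope!r}")
    kept = [
        c for c in candidates if scope == "all" or _has_repeat(c)
    ]
    counts = Counter((c.tissue, c.mismatch_type) for c in kept)
    total = len(kept)
    percentages = {
        t: percent(sum(n for (_, ty), n in counts.items() if ty == t), total)
        for t in MISMATCH_TYPES
    }
    return MismatchSummary(
        scope=scope, counts=dict(counts), total=total, percentages=percentages
    )


@dataclass
class SharingSummary:
    """Per-tissue site sets and exact Venn-cell counts.

    A site is shared between tissues when it occurs at the same physical
    position and on the same strand; ``cells`` maps each non-empty tissue
    combination to the number of sites found in exactly that combination.
    """

    tissue_sites: dict[str, set[tuple[str, int, str]]]
    cells: dict[frozenset, int]

    @property
    def union_size(self) -> int:
        out: set = set()
        for s in self.tissue_sites.values():
            out |= s
        return len(out)

    def shared_by_at_least(self, k: int) -> int:
        return sum(n for combo, n in self.cells.items() if len(combo) >= k)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"tissues": " ".join(sorted(combo)), "n_tissues": len(combo), "count": n}
            for combo, n in sorted(
                self.cells.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["tissues", "n_tissues", "count"])


def tissue_sharing(
    candidates: Iterable[Candidate],
    mismatch_type: Optional[str] = None,
) -> SharingSummary:
    """Build per-tissue (chrom, pos, strand) sets and all 2^t - 1 Venn cells.

    ``mismatch_type`` optionally restricts the input (e.g. 'A-to-G').
    Invariant under input-order permutation; cell counts sum to the size of
    the union of all per-tissue sets.
    """
    sites: dict[str, set] = {}
    for c in candidates:
        if mismatch_type is not None and c.mismatch_type != mismatch_type:
            continue
        sites.setdefault(c.tissue, set()).add((c.chrom, c.pos, c.strand))
    tissues = sorted(sites)
    cells: dict[frozenset, int] = {}
    for r in range(1, len(tissues) + 1):
        for combo in combinations(tissues, r):
            inside = set.intersection(*(sites[t] for t in combo))
            outside = set().union(
                *(sites[t] for t in tissues if t not in combo)
            ) if len(combo) < len(tissues) else set()
            cells[frozenset(combo)] = len(inside - outside)
    return SharingSummary(tissue_sites=sites, cells=cells)


@dataclass
class RepeatDistribution:
    """Two-level repeat counts with shares of all in-scope candidates."""

    total: int
    family_counts: dict[str, int]
    element_counts: dict[tuple[str, str], int]  # (family, repeat_name)

    def family_percent(self, family: str) -> float:
        return percent(self.family_counts.get(family, 0), self.total)

    def element_percent(self, repeat_name: str) -> float:
        n = sum(
            c for (_, name), c in self.element_counts.items()
            if name == repeat_name
        )
        return percent(n, self.total)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "family": fam, "repeat_name": name, "count": n,
                "percent": percent(n, self.total),
            }
            for (fam, name), n in sorted(self.element_counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["family", "repeat_name", "count", "percent"]
        )


def repeat_distribution(
    candidates: Iterable[AnnotatedCandidate],
    mismatch_type: Optional[str] = "A-to-G",
) -> RepeatDistribution:
    """Distribution of repetitive candidates over repeat families and elements.

    Only candidates inside a repeat count; percentages are out of all
    in-scope (default A-to-G) repetitive candidates.
    """
    kept = [
        c for c in candidates
        if _has_repeat(c)
        and (mismatch_type is None or c.mismatch_type == mismatch_type)
    ]
    fam = Counter(c.repeat.family for c in kept)
    elem = Counter((c.repeat.family, c.repeat.repeat_name) for c in kept)
    return RepeatDistribution(
        total=len(kept), family_counts=dict(fam), element_counts=dict(elem)
    )


def location_distribution(
    candidates: Iterable[AnnotatedCandidate],
    mismatch_type: Optional[str] = "A-to-G",
) -> pd.DataFrame:
    """Counts and percentages per genic location category.

    One row per category present in the vocabulary; percentages are over
    all in-scope (default A-to-G) candidates, one-decimal rounding.
    """
    kept = [
        c for c in candidates
        if mismatch_type is None or c.mismatch_type == mismatch_type
    ]
    counts = Counter(c.location_category for c in kept)
    total = len(kept)
    rows = [
        {
            "category": cat,
            "count": counts.get(cat, 0),
            "percent": percent(counts.get(cat, 0), total),
        }
        for cat in LOCATION_CATEGORIES
    ]
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


# ---------------------------------------------------------------------------
# Table emission (stable headers for diff-based regression tests)
# ---------------------------------------------------------------------------

def write_table(path, frame: pd.DataFrame, name: str) -> None:
    from .detection import TABLE_SCHEMA_LINE

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{TABLE_SCHEMA_LINE} {name}\n")
        frame.to_csv(fh, sep="\t", index=False)


def plot_type_counts(summary: MismatchSummary, path) -> None:
    """Bar chart of mismatch-type totals (one bar per type, count-labelled)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    totals = [summary.type_total(t) for t in MISMATCH_TYPES]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(range(len(MISMATCH_TYPES)), totals, color="#4C72B0")
    ax.set_xticks(range(len(MISMATCH_TYPES)))
    ax.set_xticklabels(MISMATCH_TYPES, rotation=60, ha="right", fontsize=8)
    ax.set_ylabel("candidates")
    ax.set_title(f"DNA-to-RNA mismatch counts ({summary.scope} sites)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
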