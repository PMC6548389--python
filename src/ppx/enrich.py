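"""Over-representation analysis against the assay-panel background.

Significant proteins are tested for enrichment in annotated term sets
(e.g. biological processes) with the one-sided hypergeometric test, using
the full profiled panel — not the genome — as the reference population.
Terms need at least three hits and a Benjamini-Hochberg q-value below 0.1
to be called enriched; the plain cross-product odds ratio is reported, with
infinities flagged rather than truncated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ValidationError
from .moderated import bh_qvalues


@dataclass(frozen=True)
class TermAnnotation:
    """One term set: identifier, human-readable name, member proteins."""

    term_id: str
    name: str
    members: frozenset

    @classmethod
    def make(cls, term_id: str, name: str, members: Iterable[str]) -> "TermAnnotation":
        return cls(term_id=term_id, name=name, members=frozenset(members))


@dataclass
class EnrichmentResult:
    """Per-term enrichment table plus the significant subset."""

    table: pd.DataFrame
    significant: pd.DataFrame
    n_hits: int
    n_background: int
    min_hits: int
    alpha_q: float


def read_gmt(path) -> list[TermAnnotation]:
    """Read GMT-format term sets (term, description, members per line)."""
    terms = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            terms.append(TermAnnotation.make(parts[0], parts[1], [p for p in parts[2:] if p]))
    return terms


def write_gmt(terms: Sequence[TermAnnotation], path) -> None:
    with open(path, "w") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.name, *sorted(t.members)]) + "\n")


def fisher_ora(hits: Iterable[str], annotation: Sequence[TermAnnotation],
               background: Iterable[str], min_hits: int = 3,
               alpha_q: float = 0.1) -> EnrichmentResult:
    """One-sided hypergeometric over-representation test per term.

    For a term with ``a`` hits among its panel members, ``p = P(X >= a)``
    under the hypergeometric null given the hit-list size and the term's
    size within the background.  q-values are BH-adjusted across all tested
    terms (those with at least one annotated panel protein).  The reported
    odds ratio is the cross-product ``ad/bc`` of the 2x2 table, infinite
    when ``b`` or ``c`` is zero.
    """
    background = set(background)
    hits = set(hits)
    stray = hits - background
    if stray:
        raise ValidationError(f"hit {sorted(stray)[0]!r} is not in the background panel")
    M = len(background)
    n_hits = len(hits)

    rows = []
    for term in annotation:
        members = term.members & background
        if not members:
            continue
        a = len(hits & members)
        b = n_hits - a
        c = len(members) - a
        d = M - a - b - c
        p = float(hypergeom.sf(a - 1, M, len(members), n_hits))
        if b * c > 0:
            odds = (a * d) / (b * c)
        else:
            odds = np.inf if a * d > 0 else 0.0
        rows.append(
            {
                "term_id": term.term_id,
                "name": term.name,
                "term_size": len(members),
                "n": a,
                "odds_ratio": odds,
                "p": p,
            }
        )
    table = pd.DataFrame(rows, columns=["term_id", "name", "term_size", "n", "odds_ratio", "p"])
    if len(table):
        table["q"] = bh_qvalues(table["p"].to_numpy())
        table = table.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
        significant = table[(table["n"] >= min_hits) & (table["q"] < alpha_q)].reset_index(
            drop=True
        )
    else:
        table["q"] = []
        significant = table
    return EnrichmentResult(
        table=table, significant=significant, n_hits=n_hits, n_background=M,
        min_hits=min_hits, alpha_q=alpha_q,
    )
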