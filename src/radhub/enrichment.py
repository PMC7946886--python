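"""Over-representation analysis with hypergeometric tests and BH FDR.

A query gene set (a module, a hub set, a candidate list) is tested against
every term of an annotation collection with the one-sided hypergeometric
test: with a universe of N genes of which K carry the term, and a query of n
genes of which k carry it, the p-value is P(X >= k) for X hypergeometric.
Fold enrichment is (k/n) / (K/N). P-values are adjusted across terms with
the Benjamini-Hochberg step-up procedure, and a term is called enriched when
its q-value is below the FDR threshold (0.05 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, TermNotSharedError, ValidationError

RESULT_COLUMNS = ("term_name", "k", "n", "K", "N", "fold_enrichment", "p_value", "q_value", "enriched")


@dataclass
class AnnotationCollection:
    """Gene-set annotations restricted to a gene universe.

    ``terms`` maps term id -> (term name, gene set); every term set is a
    subset of ``universe``. Terms that become empty (or smaller than
    ``min_term_size``) after restriction are dropped with a warning.
    """

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __len__(self) -> int:
        return len(self.terms)


def build_collection(
    terms: dict[str, tuple[str, frozenset[str]]],
    universe,
    min_term_size: int = 3,
) -> AnnotationCollection:
    """Restrict raw term sets to the universe and drop unstable small terms."""
    universe = frozenset(str(g) for g in universe)
    if not universe:
        raise ValidationError("empty gene universe")
    kept: dict[str, tuple[str, frozenset[str]]] = {}
    dropped = []
    for term_id, (name, genes) in terms.items():
        restricted = frozenset(str(g) for g in genes) & universe
        if len(restricted) >= max(1, min_term_size):
            kept[term_id] = (name, restricted)
        else:
            dropped.append(term_id)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} terms below size {min_term_size} after "
            f"universe restriction (e.g. {dropped[:3]})"
        )
    return AnnotationCollection(kept, universe)


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Parse a GMT file: tab-separated ``term_id  term_name  gene ...`` lines."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValidationError(
                f"{path}:{lineno}: GMT line needs term_id, term_name and >= 1 gene"
            )
        term_id, term_name, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if term_id in terms:
            raise ValidationError(f"{path}:{lineno}: duplicate term id {term_id!r}")
        terms[term_id] = (term_name, frozenset(genes))
    return terms


def write_gmt(terms: dict[str, tuple[str, frozenset[str]]], path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "\t".join([term_id, name, *sorted(genes)])
        for term_id, (name, genes) in sorted(terms.items())
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    The one-sided over-representation p-value: probability of drawing at
    least k annotated genes when sampling n genes from a universe of N that
    contains K annotated ones.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def hypergeometric_enrichment(
    query,
    collection: AnnotationCollection,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Test every term for over-representation in the query set.

    Returns one row per term sorted by (q, p, term_id) with columns
    term_name, k, n, K, N, fold_enrichment, p_value, q_value, enriched.
    """
    if not 0 < fdr_threshold < 1:
        raise ConfigurationError("fdr_threshold must be in (0, 1)")
    query = frozenset(str(g) for g in query) & collection.universe
    if not query:
        raise ValidationError("query does not intersect the universe")
    N = len(collection.universe)
    n = len(query)
    rows = []
    for term_id, (name, genes) in collection.terms.items():
        K = len(genes)
        if K > N:
            raise ValidationError(f"term {term_id!r} is larger than the universe")
        k = len(query & genes)
        p = hypergeom_upper_tail(k, N, K, n)
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        fold = (k / n) / (K / N)
        rows.append(
            {"term_id": term_id, "term_name": name, "k": k, "n": n, "K": K, "N": N,
             "fold_enrichment": fold, "p_value": p}
        )
    frame = pd.DataFrame(rows).set_index("term_id")
    frame["q_value"] = bh_fdr(frame["p_value"]) if len(frame) else []
    frame["enriched"] = frame["q_value"] < fdr_threshold
    frame = frame.sort_values(["q_value", "p_value", "term_id"], kind="stable")
    return frame


def average_fold_enrichment(results_by_dataset: list[pd.DataFrame], term_id: str) -> float:
    """Mean fold enrichment of a term over the networks where it is enriched.

    Only defined for terms enriched in at least two result lists; otherwise
    :class:`TermNotSharedError` is raised (an explicit signal, not a silent
    drop).
    """
    folds = [
        float(res.loc[term_id, "fold_enrichment"])
        for res in results_by_dataset
        if term_id in res.index and bool(res.loc[term_id, "enriched"])
    ]
    if len(folds) < 2:
        raise TermNotSharedError(
            f"term {term_id!r} enriched in {len(folds)} result list(s); need >= 2"
        )
    return float(np.mean(folds))


def shared_enrichment_summary(results_by_dataset: list[pd.DataFrame]) -> pd.DataFrame:
    """Average fold enrichment for every term enriched in >= 2 networks."""
    term_ids = sorted({t for res in results_by_dataset for t in res.index})
    rows = []
    for term_id in term_ids:
        try:
            avg = average_fold_enrichment(results_by_dataset, term_id)
        except TermNotSharedError:
            continue
        n_enriched = sum(
            1
            for res in results_by_dataset
            if term_id in res.index and bool(res.loc[term_id, "enriched"])
        )
        names = [
            str(res.loc[term_id, "term_name"])
            for res in results_by_dataset
            if term_id in res.index
        ]
        rows.append(
            {
                "term_id": term_id,
                "term_name": names[0] if names else "",
                "n_networks_enriched": n_enriched,
                "average_fold_enrichment": avg,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["term_id", "term_name", "n_networks_enriched", "average_fold_enrichment"]
    )
    if not frame.empty:
        frame = frame.sort_values(
            ["average_fold_enrichment", "term_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return frame
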