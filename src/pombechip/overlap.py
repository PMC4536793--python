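"""Gene-set overlap statistics for Venn-style comparisons.

For two gene lists drawn from a shared universe of N genes, the expected
overlap of random lists of the same sizes is the hypergeometric mean
|A|·|B|/N — the number reported in parentheses next to an observed
overlap — and the significance of the observed overlap is the one-sided
(enrichment) Fisher exact p-value, i.e. the hypergeometric upper tail
P(X >= observed).

The universe is always an explicit input: whether it is the set of genes
detected on the array or the whole annotation materially changes both
the expected overlap and the p-value, so no default is ever assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

from scipy.stats import hypergeom


@dataclass(frozen=True)
class OverlapResult:
    name_a: str
    name_b: str
    set_a_size: int
    set_b_size: int
    universe_size: int
    observed: int
    expected: float
    p_value: float


def expected_overlap(n_a: int, n_b: int, n_universe: int) -> float:
    """Mean overlap of two random fixed-size lists: n_a * n_b / N."""
    if n_universe <= 0:
        raise ValueError(f"universe size must be positive, got {n_universe}")
    if not (0 <= n_a <= n_universe and 0 <= n_b <= n_universe):
        raise ValueError(
            f"list sizes must lie in [0, {n_universe}], got {n_a} and {n_b}"
        )
    return n_a * n_b / n_universe


def fisher_overlap(
    set_a: set[str],
    set_b: set[str],
    universe: set[str],
    name_a: str = "A",
    name_b: str = "B",
) -> OverlapResult:
    """One-sided Fisher exact test for enrichment of the overlap.

    Equivalent to the hypergeometric upper tail P(X >= observed) with
    |A| draws from a universe containing |B| successes.
    """
    extra_a = set_a - universe
    extra_b = set_b - universe
    if extra_a or extra_b:
        raise ValueError(
            "sets must be subsets of the universe; offending ids: "
            f"{sorted(extra_a | extra_b)[:10]}"
        )
    n = len(universe)
    n_a, n_b = len(set_a), len(set_b)
    obs = len(set_a & set_b)
    # hypergeom.sf(k-1) = P(X >= k); X ~ Hypergeom(N=n, K=n_b, n=n_a)
    p = float(hypergeom.sf(obs - 1, n, n_b, n_a))
    p = min(max(p, 0.0), 1.0)
    return OverlapResult(
        name_a=name_a,
        name_b=name_b,
        set_a_size=n_a,
        set_b_size=n_b,
        universe_size=n,
        observed=obs,
        expected=expected_overlap(n_a, n_b, n),
        p_value=p,
    )


def overlap_summary(
    named_sets: dict[str, set[str]], universe: set[str]
) -> list[OverlapResult]:
    """All unordered pairwise overlaps among >= 2 named sets."""
    if len(named_sets) < 2:
        raise ValueError("need at least two named sets")
    names = list(named_sets)
    if len(set(names)) != len(names):
        raise ValueError("duplicate set names")
    return [
        fisher_overlap(named_sets[a], named_sets[b], universe, name_a=a, name_b=b)
        for a, b in combinations(names, 2)
    ]


def read_gene_list(path: str | Path) -> set[str]:
    """One id per line; blank lines and #-comments ignored."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                ids.add(s)
    return ids


def write_overlap_table(results: list[OverlapResult], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "set_a\tset_b\tsize_a\tsize_b\tuniverse\tobserved\texpected\tp_value\n"
        )
        for r in results:
            fh.write(
                f"{r.name_a}\t{r.name_b}\t{r.set_a_size}\t{r.set_b_size}\t"
                f"{r.universe_size}\t{r.observed}\t{r.expected:.4f}\t{r.p_value:.6g}\n"
            )
    return path
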