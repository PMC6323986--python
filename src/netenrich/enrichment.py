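"""Gene-set enrichment for genome-wide, value-annotated gene lists.

Three statistics are provided:

* **ORA** — classical over-representation analysis: the upper-tail
  hypergeometric probability of the overlap between a query list and a
  gene set within a background universe.

* **AFC** ("Aggregate Fold Change") — for a genome-wide input where every
  gene carries a numeric value (log fold change, abundance, ...), the
  observed statistic for a set is the mean value of its members present in
  the input.  The null is the distribution of means of same-size gene sets
  drawn uniformly without replacement from the input genes.  Small
  instances (C(n, k) up to ``exhaustive_limit`` subsets) are enumerated
  exactly; larger ones use seeded Monte-Carlo with the add-one correction
  p = (1 + #extreme) / (1 + n_perm).  The two-sided p doubles the smaller
  tail, capped at 1.

* **KS fallback** — for large sets, where AFC randomization is
  prohibitively slow, values are converted to ranks (ties get the average
  rank) and a two-sided two-sample Kolmogorov–Smirnov test compares
  in-set against out-of-set ranks; exact p when k*(n-k) <= 1e4, asymptotic
  otherwise.  A one-sample variant (in-set ranks against uniform) is
  available via ``mode="one_sample"``.

Multiple-testing correction is Benjamini–Hochberg applied separately
within each classification framework, never pooled across frameworks
(frameworks overlap heavily, so pooling would distort the FDR).
Significance is never thresholded here; filtering is a reporting concern.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ParseError, ValidationError
from .genesets import GeneSet, GeneSetCollection

logger = logging.getLogger("netenrich")

__all__ = [
    "GeneValueTable",
    "EnrichmentResult",
    "EnrichmentConfig",
    "ora_hypergeometric",
    "afc_test",
    "ks_rank_test",
    "bh_within_framework",
    "run_enrichment",
    "write_results",
]


@dataclass(frozen=True)
class GeneValueTable:
    """Genome-wide mapping gene identifier -> numeric value."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValidationError("value table needs at least 2 genes")
        for g, v in self.values.items():
            if not math.isfinite(v):
                raise ValidationError(f"non-finite value for gene {g!r}: {v!r}")

    @property
    def genes(self) -> list[str]:
        return sorted(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def arrays(self) -> tuple[list[str], np.ndarray]:
        genes = self.genes
        return genes, np.array([self.values[g] for g in genes])

    @classmethod
    def from_tsv(cls, path) -> "GeneValueTable":
        """Read a two-column (gene, value) TSV; a header row is auto-detected
        by a non-numeric second field on the first data line."""
        entries: dict[str, float] = {}
        with open(path, encoding="utf-8") as fh:
            lines = [
                (i, ln.rstrip("\n"))
                for i, ln in enumerate(fh, start=1)
                if ln.strip() and not ln.startswith("#")
            ]
        for pos, (lineno, line) in enumerate(lines):
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"line {lineno}: value table rows must have two "
                    f"tab-separated columns, got {len(fields)}"
                )
            gene, raw = fields[0].strip(), fields[1].strip()
            try:
                v = float(raw)
            except ValueError:
                if pos == 0:
                    continue  # header row
                raise ParseError(f"line {lineno}: non-numeric value {raw!r}") from None
            if gene in entries:
                raise ParseError(f"line {lineno}: duplicate gene {gene!r}")
            entries[gene] = v
        return cls(entries)

    def to_tsv(self, path, header: bool = True) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header:
                fh.write("gene\tvalue\n")
            for g in self.genes:
                fh.write(f"{g}\t{self.values[g]:.10g}\n")


@dataclass
class EnrichmentResult:
    set_id: str
    framework: str
    n_members_in_input: int
    statistic: float
    direction: str  # {"up", "down", "two-sided"}
    p_raw: float
    method: str  # {"ORA", "AFC", "KS"}
    q_bh: float | None = None
    description: str = ""
    p_up: float | None = None
    p_down: float | None = None


def ora_hypergeometric(
    query: Iterable[str], s: GeneSet, background: Iterable[str]
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of overlap between query and set.

    The set is intersected with the background before testing; the query
    must be a subset of the background.  p is the probability of an
    overlap at least as large as observed when ``|query|`` genes are drawn
    without replacement from the background.
    """
    query = set(query)
    background = set(background)
    if not background:
        raise ValidationError("background must be non-empty")
    if not query:
        raise ValidationError("query must be non-empty")
    if not query <= background:
        extra = sorted(query - background)[:5]
        raise ValidationError(
            f"query must be a subset of the background; e.g. {extra} missing"
        )
    members = s.members & background
    k = len(query & members)
    p = float(stats.hypergeom.sf(k - 1, len(background), len(members), len(query)))
    return EnrichmentResult(
        set_id=s.id,
        framework="",
        n_members_in_input=k,
        statistic=float(k),
        direction="up",
        p_raw=min(1.0, p),
        method="ORA",
        description=s.description,
    )


def _null_means_mc(
    values: np.ndarray, k: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Means of ``n_perm`` uniform size-k subsets of ``values`` (without
    replacement), vectorized in memory-bounded chunks."""
    n = values.size
    out = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(4e6 // max(n, 1)) or 1))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # random k-subsets: k smallest of m x n i.i.d. uniforms
        idx = np.argpartition(rng.random((m, n)), k - 1, axis=1)[:, :k]
        out[done : done + m] = values[idx].mean(axis=1)
        done += m
    return out


def afc_test(
    v: GeneValueTable,
    s: GeneSet,
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive_limit: int = 100_000,
    rng: np.random.Generator | None = None,
) -> EnrichmentResult | None:
    """Aggregate Fold Change permutation test for one gene set.

    The observed statistic is the mean input value over the set's members
    present in the input; the null consists of means of random same-size
    gene sets drawn from the input genes.  Returns ``None`` (with a
    logged warning) when the set does not intersect the input.

    Exact enumeration is used when C(n, k) <= ``exhaustive_limit``;
    otherwise Monte-Carlo with ``n_perm`` draws and the add-one
    correction, which requires a seed (or an explicit ``rng``) for
    reproducibility.
    """
    if n_perm < 100:
        raise ConfigError(f"n_perm must be >= 100, got {n_perm}")
    genes, values = v.arrays()
    member_idx = [i for i, g in enumerate(genes) if g in s.members]
    k = len(member_idx)
    n = len(genes)
    if k == 0:
        logger.warning("AFC: set %r has no genes in the input; skipped", s.id)
        return None
    obs = float(values[member_idx].mean())
    eps = 1e-12 * max(1.0, abs(obs))

    if math.comb(n, k) <= exhaustive_limit:
        null = np.fromiter(
            (sum(c) for c in combinations(values, k)),
            dtype=float,
            count=math.comb(n, k),
        ) / k
        total = null.size
        p_up = float(np.count_nonzero(null >= obs - eps)) / total
        p_down = float(np.count_nonzero(null <= obs + eps)) / total
    else:
        if rng is None:
            if seed is None:
                raise ConfigError(
                    "Monte-Carlo AFC requires a seed (or rng) for reproducibility"
                )
            rng = np.random.default_rng(seed)
        null = _null_means_mc(values, k, n_perm, rng)
        p_up = (1 + int(np.count_nonzero(null >= obs - eps))) / (1 + n_perm)
        p_down = (1 + int(np.count_nonzero(null <= obs + eps))) / (1 + n_perm)

    p_two = min(1.0, 2.0 * min(p_up, p_down))
    if p_up < p_down:
        direction = "up"
    elif p_down < p_up:
        direction = "down"
    else:
        direction = "two-sided"
    return EnrichmentResult(
        set_id=s.id,
        framework="",
        n_members_in_input=k,
        statistic=obs,
        direction=direction,
        p_raw=p_two,
        method="AFC",
        description=s.description,
        p_up=p_up,
        p_down=p_down,
    )


def ks_rank_test(
    v: GeneValueTable, s: GeneSet, mode: str = "two_sample"
) -> EnrichmentResult | None:
    """Rank-based Kolmogorov–Smirnov enrichment test for one gene set.

    Values are converted to ranks (average rank on ties).  In the default
    two-sample mode the in-set ranks are compared against the out-of-set
    ranks with a two-sided KS test; in one-sample mode the in-set ranks,
    rescaled to (0, 1], are compared against the uniform distribution.
    Returns ``None`` with a warning on a degenerate split (the set covers
    none or all of the input).
    """
    if mode not in ("two_sample", "one_sample"):
        raise ConfigError(f"unknown KS mode {mode!r}")
    genes, values = v.arrays()
    ranks = stats.rankdata(values)
    in_mask = np.array([g in s.members for g in genes])
    k = int(in_mask.sum())
    n = len(genes)
    if k == 0 or k == n:
        logger.warning(
            "KS: set %r gives a degenerate in/out split (k=%d of n=%d); skipped",
            s.id, k, n,
        )
        return None
    in_ranks = ranks[in_mask]
    if mode == "two_sample":
        out_ranks = ranks[~in_mask]
        method = "exact" if k * (n - k) <= 10_000 else "asymp"
        res = stats.ks_2samp(in_ranks, out_ranks, alternative="two-sided", method=method)
    else:
        res = stats.kstest(in_ranks / n, "uniform", alternative="two-sided")
    direction = "up" if float(np.median(in_ranks)) >= (n + 1) / 2 else "down"
    return EnrichmentResult(
        set_id=s.id,
        framework="",
        n_members_in_input=k,
        statistic=float(res.statistic),
        direction=direction,
        p_raw=min(1.0, float(res.pvalue)),
        method="KS",
        description=s.description,
    )


def bh_within_framework(results: Sequence[EnrichmentResult]) -> list[EnrichmentResult]:
    """Fill ``q_bh`` by the Benjamini–Hochberg step-up, separately within
    each framework; results in other frameworks are unaffected."""
    results = list(results)
    by_fw: dict[str, list[int]] = {}
    for i, r in enumerate(results):
        if not 0.0 <= r.p_raw <= 1.0:
            raise ValidationError(f"p_raw out of [0, 1] for set {r.set_id!r}")
        by_fw.setdefault(r.framework, []).append(i)
    out = list(results)
    for idxs in by_fw.values():
        p = np.array([results[i].p_raw for i in idxs])
        q = multipletests(p, method="fdr_bh")[1]
        for i, qi in zip(idxs, q):
            out[i] = replace(results[i], q_bh=float(qi))
    return out


@dataclass
class EnrichmentConfig:
    """Knobs for :func:`run_enrichment`.

    ``large_set_threshold`` — sets with more than this many members in the
    input are routed to the KS fallback instead of AFC permutation.
    """

    large_set_threshold: int = 1000
    n_perm: int = 10_000
    exhaustive_limit: int = 100_000
    seed: int | None = None
    ks_mode: str = "two_sample"


def run_enrichment(
    v: GeneValueTable,
    collections: Sequence[GeneSetCollection],
    cfg: EnrichmentConfig | None = None,
) -> list[EnrichmentResult]:
    """Test every set of every collection against the value table.

    Per set: AFC when the effective size (members present in the input) is
    at most ``cfg.large_set_threshold``, otherwise the KS fallback; then
    per-framework BH.  Results are sorted by (framework, q, p, set id).
    Frameworks with zero intersecting sets are omitted with a warning.
    """
    if cfg is None:
        cfg = EnrichmentConfig()
    if not collections:
        raise ValidationError("at least one gene-set collection is required")
    input_genes = set(v.values)
    rng = (
        np.random.default_rng(cfg.seed) if cfg.seed is not None else None
    )
    results: list[EnrichmentResult] = []
    for coll in collections:
        fw_results: list[EnrichmentResult] = []
        for s in coll:
            eff = len(s.members & input_genes)
            if eff == 0:
                logger.warning(
                    "framework %r: set %r does not intersect the input; skipped",
                    coll.framework, s.id,
                )
                continue
            if eff <= cfg.large_set_threshold:
                r = afc_test(
                    v, s,
                    n_perm=cfg.n_perm,
                    seed=cfg.seed,
                    exhaustive_limit=cfg.exhaustive_limit,
                    rng=rng,
                )
            else:
                r = ks_rank_test(v, s, mode=cfg.ks_mode)
            if r is not None:
                r.framework = coll.framework
                fw_results.append(r)
        if not fw_results:
            logger.warning(
                "framework %r has no sets intersecting the input; omitted",
                coll.framework,
            )
            continue
        results.extend(fw_results)
    results = bh_within_framework(results)
    results.sort(key=lambda r: (r.framework, r.q_bh, r.p_raw, r.set_id))
    return results


RESULT_COLUMNS = (
    "framework", "set_id", "description", "n_members_in_input",
    "statistic", "direction", "method", "p_raw", "q_bh",
)


def write_results(results: Sequence[EnrichmentResult], path) -> None:
    """Write results as TSV with a fixed column order."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            q = "" if r.q_bh is None else f"{r.q_bh:.6g}"
            fh.write(
                "\t".join([
                    r.framework, r.set_id, r.description,
                    str(r.n_members_in_input), f"{r.statistic:.6g}",
                    r.direction, r.method, f"{r.p_raw:.6g}", q,
                ]) + "\n"
            )
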