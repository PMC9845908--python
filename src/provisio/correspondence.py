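"""Cross-tissue module correspondence: relabeling, overlap, and nulls.

One tissue's module partition is relabeled against a reference partition by
greedy best-overlap matching; module-pair overlaps are tested against the
hypergeometric null (with a representation factor) and against a size-aware
bootstrap null that repeatedly draws random gene sets of the source module's
size from the assigned-gene universe and asks how often they land in the
target module at least as heavily as observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

FLOW_BANDS = [
    (0.0, 0.01, "<1%"),
    (0.01, 0.10, "1-10%"),
    (0.10, 0.20, "10-20%"),
    (0.20, 0.30, "20-30%"),
    (0.30, 0.40, "30-40%"),
    (0.40, 0.50, "40-50%"),
    (0.50, 0.60, "50-60%"),
    (0.60, 0.70, "60-70%"),
    (0.70, 1.0 + 1e-9, ">70%"),
]


@dataclass(frozen=True)
class OverlapResult:
    source_module: int
    target_module: int
    k: int
    n_source: int
    n_target: int
    universe: int
    p_hypergeom: float
    representation_factor: float

    @property
    def overlap_fraction(self) -> float:
        return self.k / self.n_source if self.n_source else 0.0


@dataclass
class BootstrapNull:
    n_iterations: int
    seed: int
    observed_proportion: float
    null_proportions: np.ndarray
    empirical_p: float
    upper_bound: bool  # True when zero exceedances: report as p < 1/n_iter

    def formatted_p(self) -> str:
        if self.upper_bound:
            return f"< {1.0 / self.n_iterations:g}"
        return f"{self.empirical_p:g}"


# ---------------------------------------------------------------------------
# hypergeometric overlap
# ---------------------------------------------------------------------------


def hypergeometric_overlap(k: int, n_source: int, n_target: int, N: int
                           ) -> tuple[float, float]:
    """Upper-tail hypergeometric p and the representation factor.

    p = P(X >= k) with X ~ Hypergeom(N, n_target, n_source); the
    representation factor is observed/expected overlap, k*N/(n_source*n_target).
    """
    if not (0 <= k <= min(n_source, n_target) and n_source <= N and n_target <= N):
        raise ValueError("inconsistent overlap counts")
    p = float(stats.hypergeom.sf(k - 1, N, n_target, n_source))
    rf = (k * N / (n_source * n_target)) if n_source and n_target else 0.0
    return min(p, 1.0), float(rf)


# ---------------------------------------------------------------------------
# label matching
# ---------------------------------------------------------------------------


def match_labels(source: pd.Series, reference: pd.Series) -> pd.Series:
    """Relabel source modules to the reference labels they best overlap.

    Greedy: repeatedly take the (source, reference) module pair with the
    smallest hypergeometric overlap p over the shared gene universe,
    relabel, and remove both from the pool.  Unmatched source modules get
    fresh labels beyond the reference's range; label 0 is never matched.
    """
    shared = source.index.intersection(reference.index)
    if shared.empty:
        raise ValueError("partitions share no genes")
    s, r = source.loc[shared], reference.loc[shared]
    n_universe = len(shared)
    src_mods = sorted(set(s) - {0})
    ref_mods = sorted(set(r) - {0})

    candidates = []
    for sm in src_mods:
        s_genes = set(shared[s == sm])
        for rm in ref_mods:
            r_genes = set(shared[r == rm])
            k = len(s_genes & r_genes)
            p, _ = hypergeometric_overlap(k, len(s_genes), len(r_genes), n_universe)
            candidates.append((p, sm, rm))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))

    mapping: dict[int, int] = {}
    used_ref: set[int] = set()
    for p, sm, rm in candidates:
        if sm in mapping or rm in used_ref:
            continue
        mapping[sm] = rm
        used_ref.add(rm)
    next_label = (max(ref_mods) if ref_mods else 0) + 1
    for sm in src_mods:
        if sm not in mapping:
            mapping[sm] = next_label
            next_label += 1
    mapping[0] = 0
    return source.map(mapping)


# ---------------------------------------------------------------------------
# bootstrap null
# ---------------------------------------------------------------------------


def bootstrap_module_overlap(
    module_size: int,
    target_genes,
    universe,
    observed_proportion: float | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
    add_one: bool = False,
) -> BootstrapNull:
    """Size-aware bootstrap null for module overlap.

    Each iteration draws ``module_size`` genes without replacement from the
    universe and records the proportion landing in the target module.  The
    empirical p is the fraction of iterations whose proportion strictly
    exceeds the observed one; with zero exceedances the result is an upper
    bound (reported as p < 1/n_iter).  ``add_one`` switches to the
    (k+1)/(n+1) estimator.
    """
    universe = pd.Index(universe)
    if universe.empty:
        raise ValueError("empty gene universe")
    target = pd.Index(target_genes)
    if not target.isin(universe).all():
        raise ValueError("target module must be a subset of the universe")
    if module_size > len(universe):
        raise ValueError("module size exceeds universe size")
    if observed_proportion is None:
        observed_proportion = len(target.intersection(universe)) / module_size
    if not 0.0 <= observed_proportion <= 1.0:
        raise ValueError("observed proportion must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    in_target = np.asarray(universe.isin(target))
    n = len(universe)
    # without-replacement draws via random-key selection, vectorized in blocks
    props = np.empty(n_iter)
    block = max(1, int(1e7 // max(n, 1)))
    done = 0
    while done < n_iter:
        b = min(block, n_iter - done)
        keys = rng.random((b, n))
        picks = np.argpartition(keys, module_size - 1, axis=1)[:, :module_size]
        props[done:done + b] = in_target[picks].mean(axis=1)
        done += b

    exceed = int((props > observed_proportion + 1e-12).sum())
    if add_one:
        p = (exceed + 1) / (n_iter + 1)
        upper = False
    else:
        p = exceed / n_iter
        upper = exceed == 0
        if upper:
            p = 1.0 / n_iter
    return BootstrapNull(
        n_iterations=n_iter,
        seed=seed,
        observed_proportion=float(observed_proportion),
        null_proportions=props,
        empirical_p=float(p),
        upper_bound=upper,
    )


# ---------------------------------------------------------------------------
# overlap table / module flow
# ---------------------------------------------------------------------------


def _flow_band(frac: float) -> str:
    for lo, hi, name in FLOW_BANDS:
        if lo <= frac < hi or (frac == 0 and lo == 0):
            return name
    return FLOW_BANDS[-1][2]


def overlap_table(
    source: pd.Series,
    reference: pd.Series,
    modules_of_interest=None,
    include_unassigned: bool = False,
    n_iter: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Full cross-tabulation of two partitions with overlap statistics.

    The universe is the set of genes assigned (label != 0 unless
    ``include_unassigned``) in BOTH partitions; the same universe feeds the
    hypergeometric and bootstrap nulls.  Returns (table, flow summary);
    bootstrap p-values are computed for source modules listed in
    ``modules_of_interest``.
    """
    shared = source.index.intersection(reference.index)
    s, r = source.loc[shared], reference.loc[shared]
    if not include_unassigned:
        keep = (s != 0) & (r != 0)
        s, r = s[keep], r[keep]
    universe = s.index
    N = len(universe)
    if N == 0:
        raise ValueError("empty shared universe")
    moi = set(modules_of_interest or [])

    rows = []
    flows: dict[str, list] = {}
    for sm in sorted(set(s) - {0} | ({0} if include_unassigned and (s == 0).any() else set())):
        s_genes = universe[s == sm]
        for rm in sorted(set(r) - {0} | ({0} if include_unassigned and (r == 0).any() else set())):
            r_genes = universe[r == rm]
            k = len(s_genes.intersection(r_genes))
            p, rf = hypergeometric_overlap(k, len(s_genes), len(r_genes), N)
            frac = k / len(s_genes) if len(s_genes) else 0.0
            row = {
                "source_module": sm,
                "target_module": rm,
                "k": k,
                "n_source": len(s_genes),
                "n_target": len(r_genes),
                "universe": N,
                "overlap_fraction": frac,
                "p_hypergeom": p,
                "representation_factor": rf,
                "flow_band": _flow_band(frac),
            }
            if sm in moi:
                boot = bootstrap_module_overlap(
                    module_size=len(s_genes),
                    target_genes=r_genes,
                    universe=universe,
                    observed_proportion=frac,
                    n_iter=n_iter,
                    seed=seed,
                )
                row["p_bootstrap"] = boot.empirical_p
                row["p_bootstrap_is_upper_bound"] = boot.upper_bound
            rows.append(row)
            if k > 0:
                flows.setdefault(str(sm), []).append(
                    {"target": int(rm), "fraction": frac, "band": _flow_band(frac)}
                )
    table = pd.DataFrame(rows)
    summary = {"universe": N, "flows": flows}
    return table, summary
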