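"""Synthetic two-tissue maternal-RNA experiment generator.

Emulates the paired oocyte / 24-h-egg design: each female contributes one
oocyte and one egg sample, across four groups (early/late season x
control/poor body condition).  Gene counts follow a negative-binomial model
with gene-wise log-normal baseline abundance, planted coexpression modules
driven by latent factors (eigengene model), planted differential-expression
effects, tissue-specific library sizes, and a shared female-level library
intercept for paired samples.  Every generator is deterministic in a single
integer seed; independent tables draw from independently spawned streams so
partial regeneration is reproducible.

Ground truth (module membership per tissue, DE sets with signs, miRNA locus
merge map, consensus target pairs, ortholog pairs) is returned alongside the
data so every downstream stage can be validated against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("earlyControl", "earlyPoor", "lateControl", "latePoor")
TISSUES = ("oocyte", "egg")

# spawn keys for per-table random streams
_STREAM_COUNTS = 0
_STREAM_MIRNA = 1
_STREAM_HITS = 2
_STREAM_TARGETS = 3

_RNA = np.array(list("ACGU"))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignSpec:
    """Experimental design: two tissues, four season-by-condition groups.

    Defaults reproduce the field study's layout: per-tissue group sizes
    6/4/6/6 (earlyControl, earlyPoor, lateControl, latePoor), i.e. 22 females
    each contributing a paired oocyte and egg sample, 44 samples total.
    """

    n_genes: int = 12770
    n_mirna_loci: int = 75
    group_sizes: tuple[int, int, int, int] = (6, 4, 6, 6)
    cages: tuple[str, str] = ("cage1", "cage2")
    paired: bool = True

    @classmethod
    def balanced(cls, samples_per_group: int = 6, **kw) -> "DesignSpec":
        return cls(group_sizes=(samples_per_group,) * 4, **kw)

    @property
    def n_females(self) -> int:
        return sum(self.group_sizes)

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_mirna_loci < 1:
            raise ValueError("n_genes and n_mirna_loci must be positive")
        if any(s < 1 for s in self.group_sizes):
            raise ValueError("all group sizes must be positive")


@dataclass(frozen=True)
class ModuleSpec:
    """Planted coexpression module structure.

    Module labels are 1-based; label 0 means background (unassigned).
    ``trait_coupled`` maps module label -> Pearson r between its latent
    factor and the season coding in oocytes.  ``cross_tissue_map`` maps an
    oocyte module label -> (egg module label, fraction of genes re-assigned
    together in the egg network), planting the convergence of several
    season-linked oocyte modules into one large egg module.
    """

    module_sizes: tuple[int, ...] = (80, 65, 50, 45, 30)
    trait_coupled: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.5, 3: 0.45, 4: 0.45}
    )
    loading_mean: float = 1.0
    loading_sd: float = 0.2
    cross_tissue_map: Mapping[int, tuple[int, float]] = field(
        default_factory=lambda: {2: (1, 0.6), 3: (1, 0.6), 4: (1, 0.6)}
    )

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def validate(self, n_genes: int) -> None:
        if sum(self.module_sizes) > n_genes:
            raise ValueError("module sizes exceed n_genes")
        for m, r in self.trait_coupled.items():
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"coupling r for module {m} outside [-1, 1]")
        for m, (t, frac) in self.cross_tissue_map.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("cross-tissue fraction outside [0, 1]")


@dataclass(frozen=True)
class DEEffect:
    genes: tuple[str, ...]
    contrast: str  # "season" | "condition" | "interaction"
    log2fc: float
    tissue: str = "oocyte"


@dataclass(frozen=True)
class NoiseSpec:
    """Count-noise model: NB dispersion, library sizes, planted DE effects.

    Library sizes are log2-normal per tissue, with a female-level intercept
    shared by the paired oocyte/egg samples.  ``n_de_up``/``n_de_down``
    genes (drawn from the background) receive the given log2 fold changes on
    the season contrast in oocytes, mirroring the strong seasonal signal.
    """

    nb_dispersion: float = 0.05
    libsize_log2_mean: Mapping[str, float] = field(
        default_factory=lambda: {"oocyte": 21.0, "egg": 21.5}
    )
    libsize_log2_sd: float = 0.25
    female_log2_sd: float = 0.10
    baseline_log2_mean: float = 2.0
    baseline_log2_sd: float = 3.0
    n_de_up: int = 30
    n_de_down: int = 20
    de_log2fc: float = 2.0
    de_contrast: str = "season"
    de_tissue: str = "oocyte"
    de_effects: tuple[DEEffect, ...] | None = None  # overrides the n_de_* defaults

    def validate(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.de_effects is not None:
            for e in self.de_effects:
                if not np.isfinite(e.log2fc):
                    raise ValueError("fold changes must be finite")


@dataclass
class GroundTruth:
    """What was planted, keyed the same way the emitted tables are."""

    modules: dict[str, pd.Series] = field(default_factory=dict)  # tissue -> gene labels
    factors: dict[str, pd.DataFrame] = field(default_factory=dict)  # tissue -> module factors
    de_up: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    de_down: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    locus_members: dict[str, list[str]] = field(default_factory=dict)
    failing_precursors: list[str] = field(default_factory=list)
    locus_mature: dict[str, str] = field(default_factory=dict)
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    target_pairs: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------


def build_metadata(design: DesignSpec) -> pd.DataFrame:
    """Per-sample design factors for both tissues, one female per pair."""
    design.validate()
    rows = []
    fem = 0
    for (gi, group) in enumerate(GROUPS):
        season = "early" if group.startswith("early") else "late"
        condition = "control" if group.endswith("Control") else "poor"
        for j in range(design.group_sizes[gi]):
            fem += 1
            female = f"F{fem:02d}"
            cage = design.cages[j % len(design.cages)]
            for tissue in TISSUES:
                rows.append(
                    {
                        "sample": f"{female}_{tissue}",
                        "tissue": tissue,
                        "season": season,
                        "condition": condition,
                        "group": group,
                        "cage": cage,
                        "female": female,
                    }
                )
    meta = pd.DataFrame(rows).set_index("sample")
    return meta


# ---------------------------------------------------------------------------
# gene counts
# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _orthogonal_noise(rng: np.random.Generator, basis: list[np.ndarray],
                      n: int) -> np.ndarray:
    """Standardized noise vector orthogonal to the constant and the basis."""
    eps = rng.standard_normal(n)
    eps = eps - eps.mean()
    for b in basis:
        eps = eps - b * (eps @ b) / (b @ b)
    if np.allclose(eps, 0):
        raise ValueError("degenerate noise vector")
    return _standardize(eps)


def _module_factors(rng: np.random.Generator, n_modules: int, season_z: np.ndarray,
                    coupling: Mapping[int, float]) -> np.ndarray:
    """Latent factor per module, row 0 unused (background).

    Factors are built on mutually orthogonal noise (also orthogonal to the
    season coding), so the planted partition is identifiable: a
    trait-coupled factor has exact sample correlation r with the season
    coding, and two factors correlate only through shared season coupling.
    """
    n = season_z.size
    z0 = _standardize(season_z)
    basis = [z0]
    factors = np.zeros((n_modules + 1, n))
    for m in range(1, n_modules + 1):
        eps = _orthogonal_noise(rng, basis, n)
        basis.append(eps)
        r = coupling.get(m, 0.0)
        factors[m] = r * z0 + np.sqrt(1.0 - r * r) * eps if r != 0.0 else eps
    return factors


def _module_labels(design: DesignSpec, modules: ModuleSpec, genes: list[str],
                   rng: np.random.Generator) -> tuple[pd.Series, pd.Series]:
    """Oocyte and egg module membership (label 0 = background)."""
    n = design.n_genes
    order = rng.permutation(n)
    oocyte = np.zeros(n, dtype=int)
    pos = 0
    for m, size in enumerate(modules.module_sizes, start=1):
        oocyte[order[pos:pos + size]] = m
        pos += size
    egg = oocyte.copy()
    for m, (target, frac) in modules.cross_tissue_map.items():
        members = np.flatnonzero(oocyte == m)
        k = int(round(frac * members.size))
        moved = rng.choice(members, size=k, replace=False)
        egg[moved] = target
    return (
        pd.Series(oocyte, index=genes, name="module"),
        pd.Series(egg, index=genes, name="module"),
    )


def generate_counts(
    design: DesignSpec = DesignSpec(),
    modules: ModuleSpec = ModuleSpec(),
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate the gene-level count matrix for both tissues.

    Returns (counts, metadata, truth); counts has genes as rows and all
    oocyte+egg samples as columns.
    """
    design.validate()
    modules.validate(design.n_genes)
    noise.validate()
    rng = _rng(seed, _STREAM_COUNTS)

    meta = build_metadata(design)
    genes = [f"g{i + 1:05d}" for i in range(design.n_genes)]
    truth = GroundTruth()

    oocyte_labels, egg_labels = _module_labels(design, modules, genes, rng)
    truth.modules = {"oocyte": oocyte_labels, "egg": egg_labels}

    # gene-wise baseline log2 abundance, shared across tissues
    mu = rng.normal(noise.baseline_log2_mean, noise.baseline_log2_sd, design.n_genes)
    gene_index_of = {g: i for i, g in enumerate(genes)}

    # planted DE effects
    effects = noise.de_effects
    if effects is None:
        n_de = noise.n_de_up + noise.n_de_down
        # plant DE only on expressed background genes: differential signal
        # in features below the detection floor is unobservable by design
        med = float(np.median(mu))
        background = [
            g for g, lab in oocyte_labels.items()
            if lab == 0 and mu[gene_index_of[g]] >= med
        ]
        if len(background) >= n_de:
            picked = rng.choice(background, size=n_de, replace=False)
        elif design.n_genes >= n_de:
            # not enough background: top up from module genes (confounds
            # module structure; only happens at very small n_genes)
            extra = [g for g in genes if g not in set(background)]
            picked = np.concatenate(
                [background, rng.choice(extra, size=n_de - len(background),
                                        replace=False)]
            )
        else:
            raise ValueError("n_genes too small for the requested DE effects")
        up = tuple(picked[: noise.n_de_up])
        down = tuple(picked[noise.n_de_up:])
        effects = (
            DEEffect(up, noise.de_contrast, noise.de_log2fc, noise.de_tissue),
            DEEffect(down, noise.de_contrast, -noise.de_log2fc, noise.de_tissue),
        )
    for e in effects:
        key = (e.tissue, e.contrast)
        store = truth.de_up if e.log2fc > 0 else truth.de_down
        if e.log2fc != 0:
            store.setdefault(key, []).extend(e.genes)

    # female-level library intercept, shared by the paired samples
    female_ids = sorted(meta["female"].unique())
    female_shift = dict(
        zip(female_ids, rng.normal(0.0, noise.female_log2_sd, len(female_ids)))
    )

    gene_index = gene_index_of
    counts = np.zeros((design.n_genes, meta.shape[0]), dtype=np.int64)

    for tissue, labels in (("oocyte", oocyte_labels), ("egg", egg_labels)):
        tmask = meta["tissue"] == tissue
        tmeta = meta[tmask]
        n_s = tmeta.shape[0]
        season_z = (tmeta["season"] == "late").to_numpy(float)
        cond_z = (tmeta["condition"] == "poor").to_numpy(float)

        # latent factor per module; trait-coupled only in oocytes
        loadings = rng.normal(modules.loading_mean, modules.loading_sd, design.n_genes)
        coupling = dict(modules.trait_coupled) if tissue == "oocyte" else {}
        factors = _module_factors(rng, modules.n_modules, season_z, coupling)
        truth.factors[tissue] = pd.DataFrame(
            factors[1:], index=[f"mod{m}" for m in range(1, modules.n_modules + 1)],
            columns=tmeta.index,
        )

        x = np.tile(mu[:, None], (1, n_s))
        lab = labels.to_numpy()
        in_mod = lab > 0
        x[in_mod] += loadings[in_mod, None] * factors[lab[in_mod]]

        for e in effects:
            if e.tissue != tissue:
                continue
            if e.contrast == "season":
                covar = season_z
            elif e.contrast == "condition":
                covar = cond_z
            elif e.contrast == "interaction":
                covar = season_z * cond_z
            else:
                raise ValueError(f"unknown contrast {e.contrast!r}")
            idx = [gene_index[g] for g in e.genes]
            x[idx] += e.log2fc * covar[None, :]

        # library sizes: tissue log-normal plus the female intercept
        lib_log2 = (
            noise.libsize_log2_mean[tissue]
            + rng.normal(0.0, noise.libsize_log2_sd, n_s)
            + np.array([female_shift[f] for f in tmeta["female"]])
        )
        libsize = 2.0 ** lib_log2

        prop = 2.0 ** x
        prop /= prop.sum(axis=0, keepdims=True)
        mean = prop * libsize[None, :]

        shape = 1.0 / noise.nb_dispersion
        lam = rng.gamma(shape, mean / shape)
        block = rng.poisson(lam)
        counts[:, np.flatnonzero(tmask.to_numpy())] = block

    count_df = pd.DataFrame(counts, index=genes, columns=meta.index)
    return count_df, meta, truth


# ---------------------------------------------------------------------------
# miRNA candidate records
# ---------------------------------------------------------------------------


def _random_rna(rng: np.random.Generator, length: int = 22) -> str:
    return "".join(rng.choice(_RNA, size=length))


def generate_mirna_records(
    n_loci: int = 75,
    duplicate_mature_fraction: float = 0.04,
    seed: int = 0,
    merged_fraction: float = 0.2,
    fail_fraction: float = 0.4,
    n_samples: int = 44,
    sample_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Candidate precursor-mature miRNA records with planted curation truth.

    ``n_loci`` is the number of loci that survive curation.  A
    ``merged_fraction`` of loci are planted as two overlapping precursors
    with identical mature sequence (must merge); a
    ``duplicate_mature_fraction`` of loci share a mature sequence with
    another locus at a disjoint genomic location (must stay separate).  A
    further ``fail_fraction`` (relative to n_loci) of decoy precursors fail
    the quality filters in every sample (rRNA/tRNA flag, randfold p >= 0.05,
    or sub-threshold star reads).
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    for frac in (duplicate_mature_fraction, merged_fraction, fail_fraction):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    rng = _rng(seed, _STREAM_MIRNA)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]

    n_merged = int(round(merged_fraction * n_loci))
    n_dup = int(round(duplicate_mature_fraction * n_loci))

    chroms = [f"scaffold{c + 1}" for c in range(8)]
    truth = GroundTruth()
    precursors = []  # (precursor_id, chrom, start, end, strand, mature, status)

    matures: list[str] = []
    seen: set[str] = set()
    for _ in range(n_loci):
        while True:
            m = _random_rna(rng)
            if m not in seen:
                seen.add(m)
                matures.append(m)
                break
    # duplicated matures: locus i copies the sequence of locus i - n_dup
    for i in range(n_dup):
        matures[n_loci - 1 - i] = matures[i]

    pid = 0
    for li in range(n_loci):
        locus_id = f"locus{li + 1:03d}"
        chrom = chroms[li % len(chroms)]
        strand = "+" if (li % 3) else "-"
        # duplicated-mature loci sit far apart even on the same chromosome
        start = 10_000 * (li + 1) + int(rng.integers(0, 1000))
        end = start + 80
        members = []
        pid += 1
        members.append((f"pre{pid:04d}", chrom, start, end, strand))
        if li < n_merged:
            pid += 1
            off = int(rng.integers(10, 60))
            members.append((f"pre{pid:04d}", chrom, start + off, end + off, strand))
        truth.locus_members[locus_id] = [m[0] for m in members]
        truth.locus_mature[locus_id] = matures[li]
        for m in members:
            precursors.append((*m, matures[li], "pass"))

    n_fail = int(round(fail_fraction * n_loci))
    fail_modes = ("rrna", "randfold", "star")
    for i in range(n_fail):
        pid += 1
        pre_id = f"pre{pid:04d}"
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = 2_000_000 + 10_000 * i
        precursors.append(
            (pre_id, chrom, start, start + 80, "+", _random_rna(rng), fail_modes[i % 3])
        )
        truth.failing_precursors.append(pre_id)

    rows = []
    for pre_id, chrom, start, end, strand, mature, status in precursors:
        randfold_p = float(rng.uniform(0.0, 0.049))
        rrna = False
        if status == "randfold":
            randfold_p = float(rng.uniform(0.05, 1.0))
        elif status == "rrna":
            rrna = True
        base = float(rng.uniform(20, 2000))
        for s in sample_ids:
            mature_n = int(rng.poisson(base))
            star_n = int(rng.poisson(max(base * 0.1, 8.0)))
            if status == "star":
                star_n = int(rng.integers(0, 5))
            rows.append(
                {
                    "sample": s,
                    "precursor": pre_id,
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "mature_seq": mature,
                    "mature_count": mature_n,
                    "star_count": star_n,
                    "randfold_p": randfold_p,
                    "rrna_trna": rrna,
                    "novel": pre_id.endswith(("1", "3", "5", "7", "9")),
                }
            )
    records = pd.DataFrame(rows)
    return records, truth


# ---------------------------------------------------------------------------
# directional similarity-hit tables (for reciprocal-best-hit calling)
# ---------------------------------------------------------------------------


def generate_hit_tables(
    n_a: int = 200,
    n_b: int = 200,
    ortholog_fraction: float = 0.6,
    seed: int = 0,
    decoy_rate: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Two directional hit tables (query, subject, evalue, bitscore).

    True ortholog pairs are mutual best hits with e-values far below any
    sensible cutoff; decoy hits always score worse than the true hit of the
    query, so an exact reciprocal-best scan recovers exactly the truth.
    """
    if not 0.0 <= ortholog_fraction <= 1.0:
        raise ValueError("ortholog_fraction must lie in [0, 1]")
    rng = _rng(seed, _STREAM_HITS)
    genes_a = [f"A{i + 1:04d}" for i in range(n_a)]
    genes_b = [f"B{i + 1:04d}" for i in range(n_b)]
    n_orth = int(round(ortholog_fraction * min(n_a, n_b)))
    perm_a = rng.permutation(n_a)[:n_orth]
    perm_b = rng.permutation(n_b)[:n_orth]

    truth = GroundTruth()
    ab_rows, ba_rows = [], []
    partner_a = {}
    partner_b = {}
    for ia, ib in zip(perm_a, perm_b):
        a, b = genes_a[ia], genes_b[ib]
        truth.ortholog_pairs.append((a, b))
        partner_a[a], partner_b[b] = b, a
        ev = 10.0 ** rng.uniform(-60, -10)
        bits = float(rng.uniform(200, 900))
        ab_rows.append((a, b, ev, bits))
        ba_rows.append((b, a, ev, bits))

    # decoys: strictly worse than the query's true hit.  For orphan queries
    # the decoy targets must be genes whose own best hit points elsewhere
    # (ortholog-bearing genes); if none exist, decoy e-values sit above any
    # sensible cutoff so no spurious reciprocal pair can fall below it.
    orth_a_genes = [genes_a[i] for i in perm_a]
    orth_b_genes = [genes_b[i] for i in perm_b]

    def _decoys(queries, orth_partner, pool_all, pool_orth, out):
        for q in queries:
            n_decoy = int(rng.poisson(decoy_rate))
            if n_decoy == 0:
                continue
            is_orphan = q not in orth_partner
            pool = pool_orth if (is_orphan and pool_orth) else pool_all
            safe = not is_orphan or bool(pool_orth)
            idx = rng.choice(len(pool), size=min(n_decoy, len(pool)), replace=False)
            for i in idx:
                t = pool[i]
                if orth_partner.get(q) == t:
                    continue
                ev = 10.0 ** rng.uniform(-8, 2) if safe else 10.0 ** rng.uniform(-3, 2)
                out.append((q, t, ev, float(rng.uniform(30, 60))))

    _decoys(genes_a, partner_a, genes_b, orth_b_genes, ab_rows)
    _decoys(genes_b, partner_b, genes_a, orth_a_genes, ba_rows)

    cols = ["query", "subject", "evalue", "bitscore"]
    return (
        pd.DataFrame(ab_rows, columns=cols),
        pd.DataFrame(ba_rows, columns=cols),
        truth,
    )


# ---------------------------------------------------------------------------
# target prediction tables (two predictors, consensus truth)
# ---------------------------------------------------------------------------


def generate_target_tables(
    mirnas: Sequence[str],
    genes: Sequence[str],
    n_consensus: int = 40,
    n_only_a: int = 30,
    n_only_b: int = 30,
    n_weak_b: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Two miRNA-target prediction tables whose qualified intersection is known.

    Table A carries score/energy (score >= 140, energy <= -20 for reported
    pairs); table B carries energy and a p-value.  ``n_weak_b`` pairs appear
    in both tables but with B's p >= 0.01, so they must not be called.
    """
    rng = _rng(seed, _STREAM_TARGETS)
    n_pairs = n_consensus + n_only_a + n_only_b + n_weak_b
    all_pairs = [(m, g) for m in mirnas for g in genes]
    if n_pairs > len(all_pairs):
        raise ValueError("not enough (miRNA, gene) pairs available")
    chosen = [all_pairs[i] for i in rng.choice(len(all_pairs), n_pairs, replace=False)]
    consensus = chosen[:n_consensus]
    only_a = chosen[n_consensus:n_consensus + n_only_a]
    only_b = chosen[n_consensus + n_only_a:n_consensus + n_only_a + n_only_b]
    weak_b = chosen[n_consensus + n_only_a + n_only_b:]

    truth = GroundTruth()
    truth.target_pairs = sorted(consensus)

    a_rows = [
        (m, g, float(rng.uniform(140, 200)), float(rng.uniform(-40, -20)))
        for m, g in consensus + only_a + weak_b
    ]
    b_rows = [
        (m, g, float(rng.uniform(-40, -20)), float(rng.uniform(0.0, 0.0099)))
        for m, g in consensus + only_b
    ] + [
        (m, g, float(rng.uniform(-40, -20)), float(rng.uniform(0.01, 1.0)))
        for m, g in weak_b
    ]
    preds_a = pd.DataFrame(a_rows, columns=["mirna", "gene", "score", "energy"])
    preds_b = pd.DataFrame(b_rows, columns=["mirna", "gene", "energy", "p"])
    return preds_a, preds_b, truth
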