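"""Synthetic-data generator and evaluation harness.

Emulates a sequencing-study simulation design: a pool of H haplotypes with
a rare-variant-rich site-frequency spectrum (minor-allele count k drawn
with probability proportional to 1/k, sites independent), diploid subjects
formed by summing two random haplotypes, a quantitative trait

    Y_i = beta_1 G_i1 + ... + beta_s G_is + 0.3 Z_i + eps_i,

with causal effects beta_j = +/- c * |log10 MAF_j| (uni- or bidirectional),
and variant 3D coordinates: neutral variants at N(0, 1) per axis, causal
variants at N(0, rho^2) — small dispersion rho means tight spatial
clustering of the signal.  Experiments measure type-I error, power, and
the sensitivity/specificity of signal-region detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .combine import WindowEngine, cauchy_combine, UntestableGeneError
from .data import IndividualData, SpatialMap, SummaryStats, VariantTable, compute_score_stats
from .scan1d import Scan1DConfig, make_1d_windows
from .setbased import MEAN, VARIANCE
from .signal import detect_signal_regions, significance_threshold
from .windows import build_window_set, Window, WindowSet

__all__ = [
    "SimConfig",
    "SimDataset",
    "simulate_haplotype_pool",
    "simulate_genotypes",
    "simulate_coordinates",
    "simulate_phenotype",
    "simulate_gene",
    "run_type1_experiment",
    "run_gene_size_experiment",
    "run_power_experiment",
    "run_signal_detection_experiment",
]

UNI = "uni"
BI = "bi"


@dataclass
class SimConfig:
    """Study conditions for the simulation experiments.

    Defaults are desk-scale (n=1000 subjects, B=1000 Monte-Carlo
    replicates, 1000 experiment replicates); the haplotype pool size,
    region length, covariate effect (0.3) and effect-size law
    c|log10 MAF| follow the simulation design the tests are evaluated
    under.  Full-scale settings (n=5000, 10^3-10^7 replicates) are
    reachable through the same fields.
    """

    n: int = 1000
    pool_size: int = 10000
    region_bp: int = 3000
    m_range: tuple = (20, 70)
    causal_fraction: float = 0.1
    effect_c: float = 0.25
    direction: str = UNI
    rho: float = 0.25
    alpha: float = 0.05
    reps: int = 1000
    B: int = 1000
    min_mac: int = 10
    coord_dim: int = 3
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 < self.causal_fraction <= 1.0):
            raise ValueError("causal_fraction must lie in (0, 1]")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.pool_size % 2:
            raise ValueError("pool_size must be even")
        if self.direction not in (UNI, BI):
            raise ValueError("direction must be 'uni' or 'bi'")

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        """Read a flat ``key = value`` config file (TOML-style scalars;
        '#' comments; ``m_range`` as two comma-separated ints)."""
        fields = {f.name: f.type for f in __import__("dataclasses").fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, val = (s.strip() for s in line.split("=", 1))
                val = val.strip("\"'")
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                if key == "m_range":
                    kwargs[key] = tuple(int(x) for x in val.split(","))
                elif key == "direction":
                    kwargs[key] = val
                elif key == "seed":
                    kwargs[key] = int(val)
                elif key in ("causal_fraction", "effect_c", "rho", "alpha"):
                    kwargs[key] = float(val)
                else:
                    kwargs[key] = int(val)
        return cls(**kwargs)


@dataclass
class SimDataset:
    """One simulated gene: genotypes, trait, coordinates, truth."""

    data: IndividualData
    variants: VariantTable
    spatial: SpatialMap
    causal_idx: np.ndarray
    beta: np.ndarray


_sfs_cache: dict[int, np.ndarray] = {}


def _sfs_cdf(kmax: int) -> np.ndarray:
    if kmax not in _sfs_cache:
        w = 1.0 / np.arange(1, kmax + 1)
        _sfs_cache[kmax] = np.cumsum(w) / w.sum()
    return _sfs_cache[kmax]


def simulate_haplotype_pool(m: int, H: int, seed=None) -> np.ndarray:
    """H x m binary haplotype pool with neutral-SFS allele counts.

    Per site the pool minor-allele count k in {1, ..., H/2} is drawn with
    P(k) proportional to 1/k and the k carriers are placed uniformly at
    random; sites are independent (no linkage disequilibrium).
    """
    if m < 2:
        raise ValueError("need at least 2 sites")
    if H % 2:
        raise ValueError("H must be even")
    rng = np.random.default_rng(seed)
    cdf = _sfs_cdf(H // 2)
    ks = np.searchsorted(cdf, rng.random(m)) + 1
    pool = np.zeros((H, m), dtype=np.int8)
    for j, k in enumerate(ks):
        carriers = rng.permutation(H)[:k]
        pool[carriers, j] = 1
    return pool


def simulate_genotypes(pool: np.ndarray, n: int, seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Diploid dosages for n subjects: sum of two pool haplotypes drawn
    uniformly with replacement.  Sample-monomorphic columns are dropped and
    columns are re-oriented to count the sample minor allele.  Returns
    (G, kept_column_indices)."""
    rng = np.random.default_rng(seed)
    H = pool.shape[0]
    idx = rng.integers(0, H, size=(n, 2))
    G = (pool[idx[:, 0]] + pool[idx[:, 1]]).astype(float)
    freq = G.mean(axis=0) / 2.0
    keep = (freq > 0.0) & (freq < 1.0)
    G = G[:, keep]
    freq = freq[keep]
    flip = freq > 0.5
    G[:, flip] = 2.0 - G[:, flip]
    return G, np.flatnonzero(keep)


def simulate_coordinates(
    m: int, causal_idx, rho: float, dim: int = 3, seed=None,
    structure_id: str = "SIM",
) -> SpatialMap:
    """Coordinates on one pseudo-structure: neutral N(0,1) per axis,
    causal N(0, rho^2) per axis."""
    if rho <= 0:
        raise ValueError("rho must be positive")
    rng = np.random.default_rng(seed)
    coords = rng.standard_normal((m, dim))
    causal_idx = np.asarray(causal_idx, dtype=np.intp)
    coords[causal_idx] *= rho
    return SpatialMap(
        structure_id=np.array([structure_id] * m, dtype=object),
        coords=coords,
    )


def simulate_phenotype(
    G: np.ndarray, maf: np.ndarray, causal_idx, c: float,
    direction: str = UNI, seed=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quantitative trait with covariate effect 0.3 and causal effects
    +/- c|log10 MAF|.  Under "bi", ceil(s/2) effects are positive and the
    rest negative (random assignment).  Returns (y, Z, beta)."""
    if c < 0:
        raise ValueError("effect scale c must be non-negative")
    rng = np.random.default_rng(seed)
    n, m = G.shape
    causal_idx = np.asarray(causal_idx, dtype=np.intp)
    beta = np.zeros(m)
    if causal_idx.size and c > 0:
        mag = c * np.abs(np.log10(maf[causal_idx]))
        signs = np.ones(causal_idx.size)
        if direction == BI:
            n_pos = int(np.ceil(causal_idx.size / 2))
            order = rng.permutation(causal_idx.size)
            signs[order[n_pos:]] = -1.0
        beta[causal_idx] = signs * mag
    Z = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    y = G @ beta + 0.3 * Z + eps
    return y, Z, beta


def simulate_gene(cfg: SimConfig, seed=None, null: bool = False) -> SimDataset:
    """One full synthetic gene under the configured conditions."""
    if seed is None:
        seed = cfg.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_pool, s_geno, s_causal, s_coord, s_pheno, s_pos = ss.spawn(6)
    rng = np.random.default_rng(s_causal)
    m0 = int(rng.integers(cfg.m_range[0], cfg.m_range[1] + 1))
    pool = simulate_haplotype_pool(m0, cfg.pool_size, seed=s_pool)
    G, kept = simulate_genotypes(pool, cfg.n, seed=s_geno)
    m = G.shape[1]
    if m < 2:
        # pathologically sparse draw; retry with a fresh spawn
        return simulate_gene(cfg, seed=ss.spawn(1)[0], null=null)
    mac = G.sum(axis=0).astype(np.int64)
    maf = mac / (2.0 * cfg.n)
    pos_rng = np.random.default_rng(s_pos)
    pos = np.sort(pos_rng.choice(cfg.region_bp, size=m, replace=False)) + 1
    variants = VariantTable(
        variant_id=np.array([f"v{j + 1}" for j in range(m)], dtype=object),
        chrom=np.array(["1"] * m, dtype=object),
        pos=pos,
        maf=maf,
        mac=mac,
    )
    if null:
        causal_idx = np.array([], dtype=np.intp)
    else:
        s = max(1, int(round(cfg.causal_fraction * m)))
        causal_idx = np.sort(rng.choice(m, size=s, replace=False))
    spatial = simulate_coordinates(
        m, causal_idx, cfg.rho, dim=cfg.coord_dim, seed=s_coord
    )
    y, Z, beta = simulate_phenotype(
        G, maf, causal_idx, 0.0 if null else cfg.effect_c,
        direction=cfg.direction, seed=s_pheno,
    )
    data = IndividualData(G=G, y=y, Z=np.column_stack([np.ones(cfg.n), Z]))
    return SimDataset(data=data, variants=variants, spatial=spatial,
                      causal_idx=causal_idx, beta=beta)


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------


def _engines_for(ds: SimDataset, stats, ws, kinds):
    out = {}
    for kind in kinds:
        try:
            out[kind] = WindowEngine(stats, ws, ds.variants, kind)
        except UntestableGeneError:
            out[kind] = None
    return out


def run_type1_experiment(
    cfg: SimConfig,
    alphas: tuple = (0.05, 0.01),
    kinds: tuple = (MEAN, VARIANCE),
) -> pd.DataFrame:
    """Empirical type-I error of signal-region detection under the null.

    Per replicate a fresh null gene is generated, the Monte-Carlo
    per-window threshold derived (B draws of U* ~ MVN(0, V)), and a
    rejection recorded when any window p-value falls below the threshold.
    Returns one row per method x alpha with the rate and its binomial SE.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rej = {(k, a): 0 for k in kinds for a in alphas}
    used = 0
    for rep_seed in ss.spawn(cfg.reps):
        child = rep_seed.spawn(2)
        ds = simulate_gene(cfg, seed=child[0], null=True)
        stats = compute_score_stats(ds.data)
        ws = build_window_set(ds.spatial, ds.variants, min_mac=cfg.min_mac)
        engines = _engines_for(ds, stats, ws, kinds)
        if any(e is None for e in engines.values()):
            continue
        used += 1
        rng = np.random.default_rng(child[1])
        for kind in kinds:
            eng = engines[kind]
            null_min = eng.pvalues_batch(eng.draw_null_scores(cfg.B, rng)).min(axis=0)
            obs_min = float(eng.pvalues_batch(stats.U[:, None]).min())
            for a in alphas:
                thr = significance_threshold(null_min, a)
                if obs_min < thr:
                    rej[(kind, a)] += 1
    rows = []
    for (kind, a), count in rej.items():
        rate = count / used
        rows.append(
            {
                "method": f"scan3d_{kind}",
                "metric": "signal_type1",
                "alpha": a,
                "value": rate,
                "se": np.sqrt(rate * (1 - rate) / used) if used else np.nan,
                "reps": used,
            }
        )
    return pd.DataFrame(rows)


def run_gene_size_experiment(
    cfg: SimConfig,
    n_genes: int = 500,
    draws_per_gene: int = 4000,
    alphas: tuple = (1e-4, 1e-2),
    kinds: tuple = (MEAN,),
) -> pd.DataFrame:
    """Empirical size of the gene-level Cauchy test under the null.

    For each synthetic gene the genotypes and covariate are held fixed and
    ``draws_per_gene`` independent null phenotype vectors are simulated;
    U, sigma^2 and every window p-value are recomputed per replicate (all
    vectorised), then combined with the Cauchy method.  Total replicates =
    n_genes * draws_per_gene.
    """
    ss = np.random.SeedSequence(cfg.seed)
    counts = {(k, a): 0 for k in kinds for a in alphas}
    total = 0
    for gene_seed in ss.spawn(n_genes):
        child = gene_seed.spawn(2)
        ds = simulate_gene(cfg, seed=child[0], null=True)
        G, Z = ds.data.G, ds.data.Z
        n = cfg.n
        stats0 = compute_score_stats(ds.data)
        ws = build_window_set(ds.spatial, ds.variants, min_mac=cfg.min_mac)
        engines = _engines_for(ds, stats0, ws, kinds)
        if any(e is None for e in engines.values()):
            continue
        rng = np.random.default_rng(child[1])
        R = draws_per_gene
        zcov = Z[:, 1]
        Y = 0.3 * zcov[:, None] + rng.standard_normal((n, R))
        XtX = Z.T @ Z
        coef = np.linalg.solve(XtX, Z.T @ Y)
        resid = Y - Z @ coef
        dof = n - np.linalg.matrix_rank(XtX)
        sigma2 = (resid**2).sum(axis=0) / dof  # (R,)
        T = G.T @ resid  # (m, R): G'r, unscaled scores
        ZtG = Z.T @ G
        Vtilde = G.T @ G - ZtG.T @ np.linalg.solve(XtX, ZtG)
        Vtilde = 0.5 * (Vtilde + Vtilde.T)
        total += R
        for kind in kinds:
            eng = engines[kind]
            pmat = np.empty((eng.n_windows, R))
            if kind == MEAN:
                # Q = (s'G'r)^2 / (sigma2 * s'Vtilde s)
                for kk, (idx, s, _) in enumerate(eng._rows):
                    num = (s @ T[idx]) ** 2
                    denom_tilde = float(s @ Vtilde[np.ix_(idx, idx)] @ s)
                    pmat[kk] = chi2.sf(num / (sigma2 * denom_tilde), df=1)
            else:
                from .qfchi2 import liu_sf
                from .setbased import variance_eigenvalues

                T2 = T**2
                for kk, (idx, omega, _) in enumerate(eng._quads):
                    lam_t = variance_eigenvalues(
                        Vtilde[np.ix_(idx, idx)], np.sqrt(omega)
                    )
                    Qs = (omega @ T2[idx]) / sigma2  # Q * sigma2, weights lam_t
                    pmat[kk] = liu_sf(Qs, lam_t)
            pmat = np.clip(pmat, 1e-300, 1.0 - 1e-16)
            tan_terms = np.where(
                pmat < 1e-15, 1.0 / (pmat * np.pi), np.tan((0.5 - pmat) * np.pi)
            )
            Q = tan_terms.mean(axis=0)
            pgene = np.clip(0.5 - np.arctan(Q) / np.pi, 1e-300, 1.0)
            big = Q > 1e15
            pgene[big] = 1.0 / (Q[big] * np.pi)
            for a in alphas:
                counts[(kind, a)] += int((pgene <= a).sum())
    rows = []
    for (kind, a), count in counts.items():
        rate = count / total
        rows.append(
            {
                "method": f"scan3d_{kind}",
                "metric": "gene_type1",
                "alpha": a,
                "value": rate,
                "se": np.sqrt(max(rate, 1.0 / total) * (1 - rate) / total),
                "reps": total,
            }
        )
    return pd.DataFrame(rows)


def _whole_gene_windowset(variants: VariantTable, min_mac: int) -> WindowSet:
    m = len(variants)
    w = Window(
        members=frozenset(range(m)), provenance="GLOBAL",
        mac=int(variants.mac.sum()),
    )
    ws = WindowSet(windows=[w], trees={}, m=m)
    from .windows import filter_windows

    return filter_windows(ws, variants, min_mac=min_mac)


_POWER_METHODS = (
    "scan3d_mean", "scan3d_variance",
    "scan1d_mean", "scan1d_variance",
    "burden", "skat",
)


def run_power_experiment(
    cfg: SimConfig,
    scenarios: list[dict] | None = None,
    alpha: float = 1e-3,
) -> pd.DataFrame:
    """Empirical power of the gene-level tests over a scenario grid.

    Each scenario overrides ``causal_fraction``, ``direction``, ``rho``
    and ``effect_c``; per replicate all six methods are evaluated on the
    same dataset with the Cauchy combination (whole-gene burden and SKAT
    are the single-window special cases).
    """
    if scenarios is None:
        scenarios = [
            {"causal_fraction": 0.1, "direction": UNI, "rho": 0.1, "effect_c": 0.3},
            {"causal_fraction": 0.5, "direction": UNI, "rho": 1.0, "effect_c": 0.15},
            {"causal_fraction": 0.5, "direction": BI, "rho": 0.25, "effect_c": 0.15},
        ]
    rows = []
    ss = np.random.SeedSequence(cfg.seed)
    for sc_i, sc in enumerate(scenarios):
        sc_cfg = replace(cfg, **sc)
        hits = dict.fromkeys(_POWER_METHODS, 0)
        used = 0
        for rep_seed in ss.spawn(len(scenarios) * cfg.reps)[sc_i :: len(scenarios)][: cfg.reps]:
            ds = simulate_gene(sc_cfg, seed=rep_seed, null=False)
            stats = compute_score_stats(ds.data)
            sets = {
                "scan3d": build_window_set(ds.spatial, ds.variants, min_mac=cfg.min_mac),
                "scan1d": make_1d_windows(
                    ds.variants.pos, Scan1DConfig(), variants=ds.variants, min_mac=cfg.min_mac
                ),
                "gene": _whole_gene_windowset(ds.variants, cfg.min_mac),
            }
            ps = {}
            try:
                for name, ws in sets.items():
                    for kind in (MEAN, VARIANCE):
                        eng = WindowEngine(stats, ws, ds.variants, kind)
                        pw = eng.pvalues(stats.U, refine="saddlepoint")
                        ps[(name, kind)] = cauchy_combine(pw)
            except UntestableGeneError:
                continue
            used += 1
            keymap = {
                "scan3d_mean": ("scan3d", MEAN), "scan3d_variance": ("scan3d", VARIANCE),
                "scan1d_mean": ("scan1d", MEAN), "scan1d_variance": ("scan1d", VARIANCE),
                "burden": ("gene", MEAN), "skat": ("gene", VARIANCE),
            }
            for meth, key in keymap.items():
                if ps[key] <= alpha:
                    hits[meth] += 1
        for meth in _POWER_METHODS:
            rate = hits[meth] / used if used else np.nan
            rows.append(
                {"method": meth, "metric": "power", "alpha": alpha, "value": rate,
                 "se": np.sqrt(rate * (1 - rate) / used) if used else np.nan,
                 "reps": used, **sc}
            )
    return pd.DataFrame(rows)


_SIGNAL_METHODS = ("scan3d_mean", "scan3d_variance", "scan1d_mean", "scan1d_variance", "sv")


def run_signal_detection_experiment(
    cfg: SimConfig,
    scenarios: list[dict] | None = None,
) -> pd.DataFrame:
    """Sensitivity and specificity of signal-region detection.

    sensitivity = fraction of causal variants inside detected regions;
    specificity = fraction of neutral variants outside detected regions;
    both averaged over replicates.  The single-variant (SV) comparator
    tests each variant's score statistic with a per-gene Bonferroni
    correction at level alpha.
    """
    if scenarios is None:
        # the signal-detection grid: sparse/dense causal fractions with the
        # matching effect scales, at low and medium spatial dispersion
        scenarios = [
            {"causal_fraction": 0.1, "direction": UNI, "rho": 0.1, "effect_c": 0.25},
            {"causal_fraction": 0.1, "direction": UNI, "rho": 0.25, "effect_c": 0.25},
            {"causal_fraction": 0.5, "direction": UNI, "rho": 0.1, "effect_c": 0.1},
            {"causal_fraction": 0.5, "direction": UNI, "rho": 0.25, "effect_c": 0.1},
        ]
    rows = []
    ss = np.random.SeedSequence(cfg.seed)
    for sc_i, sc in enumerate(scenarios):
        sc_cfg = replace(cfg, **sc)
        sens = {m: [] for m in _SIGNAL_METHODS}
        spec = {m: [] for m in _SIGNAL_METHODS}
        for rep_seed in ss.spawn(len(scenarios) * cfg.reps)[sc_i :: len(scenarios)][: cfg.reps]:
            child = rep_seed.spawn(2)
            ds = simulate_gene(sc_cfg, seed=child[0], null=False)
            stats = compute_score_stats(ds.data)
            m = len(ds.variants)
            causal = set(int(i) for i in ds.causal_idx)
            neutral = set(range(m)) - causal
            if not causal or not neutral:
                continue
            rng = np.random.default_rng(child[1])
            sets = {
                "scan3d": build_window_set(ds.spatial, ds.variants, min_mac=cfg.min_mac),
                "scan1d": make_1d_windows(
                    ds.variants.pos, Scan1DConfig(), variants=ds.variants, min_mac=cfg.min_mac
                ),
            }
            for name, ws in sets.items():
                for kind in (MEAN, VARIANCE):
                    try:
                        eng = WindowEngine(stats, ws, ds.variants, kind)
                    except UntestableGeneError:
                        sens[f"{name}_{kind}"].append(0.0)
                        spec[f"{name}_{kind}"].append(1.0)
                        continue
                    null_min = eng.pvalues_batch(
                        eng.draw_null_scores(cfg.B, rng)
                    ).min(axis=0)
                    thr = significance_threshold(null_min, cfg.alpha)
                    obs = eng.pvalues_batch(stats.U[:, None]).ravel()
                    report = detect_signal_regions(
                        list(zip(eng.windows, obs)), thr, alpha=cfg.alpha
                    )
                    detected = set().union(*report.member_sets()) if report.regions else set()
                    sens[f"{name}_{kind}"].append(len(detected & causal) / len(causal))
                    spec[f"{name}_{kind}"].append(len(neutral - detected) / len(neutral))
            # single-variant comparator, Bonferroni within the gene
            z2 = stats.U**2 / np.clip(np.diag(stats.V), 1e-300, None)
            psv = chi2.sf(z2, df=1)
            detected = set(int(i) for i in np.flatnonzero(psv < cfg.alpha / m))
            sens["sv"].append(len(detected & causal) / len(causal))
            spec["sv"].append(len(neutral - detected) / len(neutral))
        for meth in _SIGNAL_METHODS:
            for metric, store in (("sensitivity", sens), ("specificity", spec)):
                vals = store[meth]
                rows.append(
                    {"method": meth, "metric": metric, "alpha": cfg.alpha,
                     "value": float(np.mean(vals)) if vals else np.nan,
                     "se": float(np.std(vals) / np.sqrt(len(vals))) if vals else np.nan,
                     "reps": len(vals), **sc}
                )
    return pd.DataFrame(rows)
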