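"""Synthetic genotype/trait/environment generator.

Everything needed to exercise the pipeline without external data: biallelic
dosage panels at chosen allele frequencies (outbred or fully homozygous),
additive(+dominance) traits at a controlled heritability with ground truth
returned, multi-environment daily weather series with environment-specific
trait shifts, and factorial inbred cross populations with enumerated F1s.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from autogs.genotype_io import (
    MISSING,
    GenotypeMatrix,
    PhenotypeTable,
    VariantTable,
)
from autogs.models.environment import ENV_VARIABLES


@dataclass
class SimConfig:
    n: int = 100
    L: int = 50
    maf: tuple[float, float] = (0.1, 0.5)
    n_qtl: int = 10
    effect_scale: float = 1.0
    h2: float = 0.5
    dominance_ratio: float = 0.0
    n_env: int = 0
    env_effect_scale: float = 1.0
    inbred: bool = False
    missing_rate: float = 0.0
    filter_violation_rate: float = 0.0
    ld_block_size: int = 1  # 1 = independent loci
    ld_rho: float = 0.9  # within-block copy probability
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("MAF range must satisfy 0 < lo <= hi <= 0.5")
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError("h2 must lie in (0, 1]")
        if self.n_qtl > self.L:
            raise ValueError("n_qtl cannot exceed L")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.ld_block_size < 1 or not (0.0 <= self.ld_rho <= 1.0):
            raise ValueError("ld_block_size must be >= 1 and ld_rho in [0, 1]")


def _f32(x: np.ndarray) -> np.ndarray:
    # round so values survive the float32 INFO/QUAL round trip exactly
    return np.float32(np.round(x, 3)).astype(np.float64)


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, VariantTable]:
    """Independent biallelic loci with synthetic INFO metrics.

    Outbred mode draws dosage ~ Binomial(2, p); inbred mode draws {0, 2}
    with probabilities (1-p, p).  A ``filter_violation_rate`` fraction of
    loci gets one randomly chosen quality metric pushed past its
    hard-filter bound.
    """
    rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(cfg.maf[0], cfg.maf[1], size=cfg.L)

    def _draw(j: int) -> np.ndarray:
        if cfg.inbred:
            return 2 * (rng.random(cfg.n) < p[j]).astype(np.int8)
        return rng.binomial(2, p[j], size=cfg.n).astype(np.int8)

    if cfg.ld_block_size == 1:
        cols = [_draw(j) for j in range(cfg.L)]
    else:
        # linkage blocks: within a block each locus copies its left
        # neighbour per sample with probability ld_rho
        cols = []
        for j in range(cfg.L):
            fresh = _draw(j)
            if j % cfg.ld_block_size == 0:
                cols.append(fresh)
            else:
                copy = rng.random(cfg.n) < cfg.ld_rho
                cols.append(np.where(copy, cols[-1], fresh).astype(np.int8))
    dosage = np.stack(cols, axis=1)
    if cfg.missing_rate > 0:
        mask = rng.random((cfg.n, cfg.L)) < cfg.missing_rate
        # keep at least one observed genotype per locus so imputation works
        all_gone = mask.all(axis=0)
        mask[0, all_gone] = False
        dosage[mask] = MISSING

    metrics = {
        "qual": _f32(rng.uniform(50, 100, cfg.L)),
        "QD": _f32(rng.uniform(10, 30, cfg.L)),
        "FS": _f32(rng.uniform(0, 30, cfg.L)),
        "MQ": _f32(rng.uniform(50, 60, cfg.L)),
        "SOR": _f32(rng.uniform(0.5, 2.0, cfg.L)),
        "MQRankSum": _f32(rng.uniform(-3, 3, cfg.L)),
    }
    if cfg.filter_violation_rate > 0:
        bad = rng.random(cfg.L) < cfg.filter_violation_rate
        which = rng.integers(0, 6, cfg.L)
        ranges = {
            "QD": (0.0, 1.9), "qual": (5.0, 29.0), "FS": (61.0, 100.0),
            "MQ": (10.0, 39.0), "SOR": (3.1, 9.0), "MQRankSum": (-20.0, -12.6),
        }
        for i, (name, (lo, hi)) in enumerate(ranges.items()):
            sel = bad & (which == i)
            metrics[name][sel] = _f32(rng.uniform(lo, hi, int(sel.sum())))

    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, cfg.L)
    alt_i = (ref_i + rng.integers(1, 4, cfg.L)) % 4
    pos = np.arange(1, cfg.L + 1) * 100
    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pos,
            "ref": bases[ref_i],
            "alt": bases[alt_i],
            "qual": metrics["qual"],
            "QD": metrics["QD"],
            "FS": metrics["FS"],
            "MQ": metrics["MQ"],
            "SOR": metrics["SOR"],
            "MQRankSum": metrics["MQRankSum"],
            "missing_rate": (dosage == MISSING).mean(axis=0),
        }
    )
    vt = VariantTable(df)
    samples = [f"s{i:04d}" for i in range(cfg.n)]
    gm = GenotypeMatrix(samples=samples, loci=vt.locus_keys, dosage=dosage)
    return gm, vt


@dataclass
class TraitTruth:
    beta: np.ndarray  # (L,) additive effects, zero off-QTL
    dom: np.ndarray  # (L,) dominance effects
    qtl: np.ndarray  # QTL locus indices
    genetic: np.ndarray  # (n,) true genetic values
    realized_h2: float


def genetic_values(dosage: np.ndarray, beta: np.ndarray, dom: np.ndarray) -> np.ndarray:
    d = dosage.astype(np.float64)
    return d @ beta + (d == 1.0) @ dom


def simulate_trait(
    gm: GenotypeMatrix, cfg: SimConfig, *, env: np.ndarray | None = None
) -> tuple[PhenotypeTable, TraitTruth]:
    """Additive(+dominance) trait with the realized heritability pinned to
    the target: residuals are centered, de-correlated from the genetic
    values, and rescaled so Var(genetic)/Var(y) = h2 exactly on the sample.
    """
    if gm.has_missing():
        raise ValueError("simulate_trait requires an imputed genotype matrix")
    rng = np.random.default_rng(cfg.seed + 1)
    beta = np.zeros(gm.n_loci)
    qtl = rng.choice(gm.n_loci, size=cfg.n_qtl, replace=False)
    beta[qtl] = rng.normal(0.0, cfg.effect_scale, size=cfg.n_qtl)
    dom = np.zeros(gm.n_loci)
    if cfg.dominance_ratio > 0:
        dom[qtl] = rng.normal(0.0, cfg.dominance_ratio * cfg.effect_scale, size=cfg.n_qtl)
    g = genetic_values(gm.dosage, beta, dom)
    var_g = float(g.var())
    if var_g == 0.0:
        raise ValueError("degenerate simulation: genetic variance is zero")
    if cfg.h2 >= 1.0:
        eps = np.zeros(gm.n_samples)
    else:
        eps = rng.normal(0.0, 1.0, gm.n_samples)
        eps -= eps.mean()
        gc = g - g.mean()
        eps -= gc * (eps @ gc) / (gc @ gc)  # exact zero sample covariance
        target_var_e = var_g * (1.0 - cfg.h2) / cfg.h2
        eps *= np.sqrt(target_var_e / eps.var())
    y = g + eps
    if env is not None:
        y = y + np.asarray(env, dtype=np.float64)
    realized = var_g / float((g + eps).var())
    df = pd.DataFrame({"sample": gm.samples, "value": y})
    return PhenotypeTable(df), TraitTruth(
        beta=beta, dom=dom, qtl=qtl, genetic=g, realized_h2=realized
    )


def simulate_environments(
    cfg: SimConfig, n_days: int = 60, noise: float = 0.0
) -> tuple[pd.DataFrame, dict[str, float], np.ndarray]:
    """Daily weather series per environment plus linear trait shifts.

    Each variable follows a seasonal sinusoid with an environment-specific
    offset (plus optional day-to-day noise).  The trait shift of an
    environment is a fixed linear function of its mean maximum temperature
    and mean solar radiation, so environment-aware models have signal to
    recover; the generating coefficients are returned.
    """
    if cfg.n_env < 1:
        raise ValueError("simulate_environments requires n_env >= 1")
    rng = np.random.default_rng(cfg.seed + 2)
    days = np.arange(n_days)
    baselines = {
        "tempmax": 28.0, "tempmin": 16.0, "humidity": 60.0, "precip": 3.0,
        "windspeed": 10.0, "sealevelpressure": 1013.0, "cloudcover": 40.0,
        "solarradiation": 200.0, "solarenergy": 18.0, "uvindex": 6.0,
        "sunlightduration": 12.0,
    }
    amps = {
        "tempmax": 4.0, "tempmin": 3.0, "humidity": 10.0, "precip": 2.0,
        "windspeed": 3.0, "sealevelpressure": 5.0, "cloudcover": 15.0,
        "solarradiation": 40.0, "solarenergy": 4.0, "uvindex": 2.0,
        "sunlightduration": 1.5,
    }
    env_ids = [f"env{k}" for k in range(cfg.n_env)]
    dates = pd.date_range("2024-01-01", periods=n_days).strftime("%Y-%m-%d")
    rows = []
    means = {}
    for e in env_ids:
        offsets = {v: rng.normal(0.0, 0.3 * amps[v]) for v in ENV_VARIABLES}
        series = {}
        for v in ENV_VARIABLES:
            phase = rng.uniform(0, 2 * np.pi)
            s = (
                baselines[v]
                + offsets[v]
                + amps[v] * np.sin(2 * np.pi * days / 365.0 + phase)
            )
            if noise > 0:
                s = s + rng.normal(0.0, noise * amps[v], n_days)
            series[v] = s
        for d in days:
            rows.append({"env": e, "date": dates[d],
                         **{v: series[v][d] for v in ENV_VARIABLES}})
        means[e] = np.array([series["tempmax"].mean(), series["solarradiation"].mean()])
    # shift = c0 + c1 * mean(tempmax) + c2 * mean(solarradiation)
    coeffs = np.array([0.0, cfg.env_effect_scale, 0.05 * cfg.env_effect_scale])
    shifts = {
        e: float(coeffs[0] + coeffs[1] * m[0] + coeffs[2] * m[1])
        for e, m in means.items()
    }
    center = float(np.mean(list(shifts.values())))
    shifts = {e: s - center for e, s in shifts.items()}
    return pd.DataFrame(rows), shifts, coeffs


def simulate_multi_env_trait(
    gm: GenotypeMatrix, cfg: SimConfig, n_days: int = 60
) -> tuple[PhenotypeTable, TraitTruth, dict[str, pd.DataFrame], dict[str, float]]:
    """Trait with an additive per-environment shift; samples are assigned
    to the ``n_env`` environments round-robin."""
    env_df, shifts, _ = simulate_environments(cfg, n_days=n_days)
    env_ids = sorted(shifts)
    assign = [env_ids[i % len(env_ids)] for i in range(gm.n_samples)]
    shift_vec = np.array([shifts[e] for e in assign])
    pt, truth = simulate_trait(gm, cfg, env=shift_vec)
    df = pt.df.copy()
    df["env"] = assign
    series = {
        e: grp.sort_values("date")[list(ENV_VARIABLES)].reset_index(drop=True)
        for e, grp in env_df.groupby("env")
    }
    return PhenotypeTable(df), truth, series, shifts


@dataclass
class CrossSim:
    panel: GenotypeMatrix  # inbred parents (females then males)
    female_ids: list[str]
    male_ids: list[str]
    plan: list[tuple[str, str]]
    f1: GenotypeMatrix
    f1_phenotypes: PhenotypeTable
    truth: TraitTruth
    best_pair: tuple[str, str]  # argmax of true F1 genetic value


def simulate_cross_population(
    n_female: int, n_male: int, cfg: SimConfig
) -> CrossSim:
    """Factorial cross of homozygous parents with F1 traits and ground truth."""
    from autogs.workflows import make_f1_genotype

    panel_cfg = SimConfig(
        n=n_female + n_male, L=cfg.L, maf=cfg.maf, n_qtl=cfg.n_qtl,
        effect_scale=cfg.effect_scale, h2=cfg.h2,
        dominance_ratio=cfg.dominance_ratio, inbred=True, seed=cfg.seed,
    )
    panel, _ = simulate_genotypes(panel_cfg)
    female_ids = [f"F{i:03d}" for i in range(n_female)]
    male_ids = [f"M{i:03d}" for i in range(n_male)]
    panel = GenotypeMatrix(
        samples=female_ids + male_ids, loci=panel.loci, dosage=panel.dosage
    )
    plan = [(f, m) for f in female_ids for m in male_ids]
    idx = {s: i for i, s in enumerate(panel.samples)}
    f1_dosage = np.stack(
        [make_f1_genotype(panel.dosage[idx[f]], panel.dosage[idx[m]]) for f, m in plan]
    )
    f1 = GenotypeMatrix(
        samples=[f"{f}x{m}" for f, m in plan], loci=panel.loci, dosage=f1_dosage
    )
    pt, truth = simulate_trait(f1, panel_cfg)
    best = plan[int(np.argmax(truth.genetic))]
    return CrossSim(
        panel=panel, female_ids=female_ids, male_ids=male_ids, plan=plan,
        f1=f1, f1_phenotypes=pt, truth=truth, best_pair=best,
    )
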