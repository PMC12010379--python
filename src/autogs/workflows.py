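"""End-to-end workflows: train, predict, combined train+predict, optimal
parent selection, and combined train+select.

Each run composes VCF ingestion -> optional regulatory-window selection ->
hard filtering/imputation -> encoding -> model fitting or prediction, and
emits a JSON manifest recording inputs (hashed), seed, model spec, and
output hashes.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

import autogs
from autogs.genotype_io import (
    FilterConfig,
    GenotypeMatrix,
    filter_variants,
    impute_missing,
    intersect_samples,
    read_phenotypes,
    read_vcf,
    write_predictions,
)
from autogs.models.environment import read_env_csv
from autogs.models.pool import ModelSpec
from autogs.regulatory import build_windows, load_genes, select_snps
from autogs.training import (
    ModelWeights,
    TrainOptions,
    WeightsError,
    load_weights,
    save_weights,
    train,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Wraps an error with the pipeline stage where it occurred."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapper
    return deco


# ----------------------------------------------------------------------
# F1 construction and parent selection


def make_f1_genotype(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Expected F1 dosage of a cross: (pa + pb) / 2 per locus.

    For homozygous (inbred) parents this is the exact Mendelian outcome
    (0x0 -> 0, 2x2 -> 2, 0x2 -> 1).  A heterozygous parent locus triggers a
    warning; the expected-dosage rule is still applied, rounded to the
    nearest integer dosage (x.5 rounds down toward the reference allele).
    """
    pa = np.asarray(pa)
    pb = np.asarray(pb)
    if pa.shape != pb.shape:
        raise ValueError("parent dosage vectors differ in length")
    if (pa < 0).any() or (pb < 0).any():
        raise ValueError("parent genotypes contain missing entries; impute first")
    het = (pa == 1) | (pb == 1)
    if het.any():
        warnings.warn(
            f"{int(het.sum())} heterozygous parent loci in cross; "
            "expected-dosage rule applied",
            stacklevel=2,
        )
    expected = (pa.astype(np.float64) + pb.astype(np.float64)) / 2.0
    return np.ceil(expected - 0.5).astype(np.int8)  # x.5 rounds down


@dataclass
class RankedCrosses:
    """Predicted F1 values for candidate crosses, ranked by direction."""

    table: pd.DataFrame  # female, male, predicted, rank, top5
    direction: str

    @property
    def top5(self) -> pd.DataFrame:
        return self.table[self.table["top5"]]


def select_parents(
    panel: GenotypeMatrix,
    plan: list[tuple[str, str]],
    weights: ModelWeights,
    direction: str = "maximize",
    *,
    f1: GenotypeMatrix | None = None,
    env_series=None,
    env_ids=None,
) -> RankedCrosses:
    """Predict and rank candidate crosses; the best 5 are flagged.

    F1 genotypes are constructed from the panel unless ``f1`` supplies
    pre-made ones (keyed '<female>x<male>').  Ties break deterministically
    by (female id, male id).
    """
    if direction not in ("maximize", "minimize"):
        raise ValueError("direction must be 'maximize' or 'minimize'")
    if not plan:
        raise ValueError("empty cross plan")
    if len(set(plan)) != len(plan):
        raise ValueError("duplicate pairs in cross plan")
    idx = {s: i for i, s in enumerate(panel.samples)}
    for f, m in plan:
        for pid in (f, m):
            if pid not in idx:
                raise ValueError(f"unknown parent id {pid!r} in cross plan")
    if f1 is None:
        dosage = np.stack(
            [make_f1_genotype(panel.dosage[idx[f]], panel.dosage[idx[m]]) for f, m in plan]
        )
        f1 = GenotypeMatrix(
            samples=[f"{f}x{m}" for f, m in plan],
            loci=list(panel.loci),
            dosage=dosage,
        )
    else:
        want = [f"{f}x{m}" for f, m in plan]
        pos = {s: i for i, s in enumerate(f1.samples)}
        missing = [s for s in want if s not in pos]
        if missing:
            raise ValueError(f"supplied F1 matrix lacks crosses: {missing[:5]}")
        f1 = f1.subset_samples([pos[s] for s in want])

    pred = predict_from_weights(weights, f1, env_series=env_series, env_ids=env_ids)
    df = pd.DataFrame(
        {"female": [p[0] for p in plan], "male": [p[1] for p in plan], "predicted": pred}
    )
    asc = direction == "minimize"
    df = df.sort_values(
        by=["predicted", "female", "male"], ascending=[asc, True, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["top5"] = df["rank"] <= 5
    return RankedCrosses(table=df, direction=direction)


def predict_from_weights(w, gm, **kw):
    """Locus-aligning wrapper around :func:`autogs.training.predict_from_weights`."""
    from autogs import training

    aligned = align_to_locus_map(gm, w.locus_map)
    return training.predict_from_weights(w, aligned, **kw)


def align_to_locus_map(gm: GenotypeMatrix, locus_map: list[str]) -> GenotypeMatrix:
    """Reorder/subset a genotype matrix to a trained model's locus keys."""
    if list(gm.loci) == list(locus_map):
        return gm
    pos = {k: i for i, k in enumerate(gm.loci)}
    missing = [k for k in locus_map if k not in pos]
    if missing:
        raise WeightsError(
            f"genotypes lack {len(missing)} of the {len(locus_map)} training loci "
            f"(e.g. {missing[:3]}); refusing to predict"
        )
    return gm.subset_loci([pos[k] for k in locus_map])


# ----------------------------------------------------------------------
# file-level runs


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(path, command: str, inputs: dict, outputs: dict, seed: int,
                    config: dict) -> dict:
    manifest = {
        "command": command,
        "seed": seed,
        "config": config,
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in inputs.items()},
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in outputs.items()},
        "versions": {"autogs": autogs.__version__, "numpy": np.__version__},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=1)
    return manifest


@_stage("load-genotypes")
def _load_training_genotypes(vcf_path, genes_path, up, down, strand_aware,
                             filter_config, do_filter):
    gm, vt = read_vcf(vcf_path)
    if do_filter:
        keep = filter_variants(vt, filter_config)
        gm, vt = gm.subset_loci(keep), vt.subset(keep)
    if genes_path is not None:
        genes = load_genes(genes_path)
        windows = build_windows(genes, up=up, down=down, strand_aware=strand_aware)
        sel = select_snps(vt, windows)
        gm, vt = gm.subset_loci(sel), vt.subset(sel)
    if gm.n_loci == 0:
        raise ValueError("no loci remain after filtering/selection")
    gm = impute_missing(gm)
    return gm, vt


def run_train(
    vcf_path,
    pheno_path,
    weights_out,
    spec: ModelSpec,
    options: TrainOptions | None = None,
    *,
    genes_path=None,
    up: int = 2000,
    down: int = 1000,
    strand_aware: bool = True,
    filter_config: FilterConfig | None = None,
    do_filter: bool = True,
    env_csv=None,
    manifest_out=None,
) -> dict:
    """Train a model from files and write the weights archive + manifest."""
    gm, vt = _load_training_genotypes(vcf_path, genes_path, up, down, strand_aware,
                                      filter_config, do_filter)
    try:
        pt = read_phenotypes(pheno_path)
        g_idx, p_idx = intersect_samples(gm, pt)
        if len(g_idx) == 0:
            raise ValueError("no samples shared between genotypes and phenotypes")
        gm_t = gm.subset_samples(g_idx)
        y = pt.df["value"].to_numpy()[p_idx]
    except StageError:
        raise
    except Exception as exc:
        raise StageError("load-phenotypes", exc) from exc

    env_series = env_ids = None
    if spec.uses_environment:
        if env_csv is None:
            raise StageError(
                "environment", ValueError("model EnvSE requires an environment CSV (--env)")
            )
        if not pt.has_env:
            raise StageError(
                "environment", ValueError("phenotype CSV lacks the 'env' column needed by EnvSE")
            )
        env_series = read_env_csv(env_csv)
        env_ids = list(pt.df["env"].to_numpy()[p_idx])

    try:
        w = train(spec, gm_t, y, options, env_series=env_series, env_ids=env_ids)
        save_weights(w, weights_out)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("train", exc) from exc

    inputs = {"vcf": vcf_path, "phenotypes": pheno_path}
    if genes_path is not None:
        inputs["genes"] = genes_path
    if env_csv is not None:
        inputs["environment"] = env_csv
    manifest = _write_manifest(
        manifest_out, "train", inputs, {"weights": weights_out}, spec.seed,
        {"spec": spec.to_dict(), "r_test": None if np.isnan(w.r_test) else w.r_test},
    )
    manifest["r_test"] = w.r_test
    return manifest


def run_predict(
    vcf_path,
    weights_path,
    predictions_out,
    *,
    env_csv=None,
    env_assign_path=None,
    manifest_out=None,
) -> dict:
    """Predict phenotypes for a VCF with a trained weights archive."""
    try:
        w = load_weights(weights_path)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("load-weights", exc) from exc
    try:
        gm, _ = read_vcf(vcf_path)
        gm = align_to_locus_map(gm, w.locus_map)
        gm = impute_missing(gm)
    except Exception as exc:
        raise StageError("load-genotypes", exc) from exc

    env_series = env_ids = None
    table = pd.DataFrame({"sample": gm.samples})
    if w.spec.uses_environment:
        if env_csv is None or env_assign_path is None:
            raise StageError(
                "environment",
                ValueError("EnvSE prediction requires --env (series CSV) and "
                           "--env-assign (sample,env CSV)"),
            )
        env_series = read_env_csv(env_csv)
        assign = pd.read_csv(env_assign_path, dtype=str)
        assign.columns = [c.strip().lower() for c in assign.columns]
        mapping = dict(zip(assign["sample"], assign["env"]))
        missing = [s for s in gm.samples if s not in mapping]
        if missing:
            raise StageError(
                "environment",
                ValueError(f"samples without an environment assignment: {missing[:5]}"),
            )
        env_ids = [mapping[s] for s in gm.samples]
        table["env"] = env_ids

    try:
        from autogs import training

        pred = training.predict_from_weights(w, gm, env_series=env_series, env_ids=env_ids)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("predict", exc) from exc
    table["predicted"] = pred
    write_predictions(table, predictions_out)
    inputs = {"vcf": vcf_path, "weights": weights_path}
    if env_csv is not None:
        inputs["environment"] = env_csv
    return _write_manifest(
        manifest_out, "predict", inputs, {"predictions": predictions_out},
        w.spec.seed, {"spec": w.spec.to_dict()},
    )


def run_train_predict(
    vcf_path, pheno_path, weights_out, predictions_out, spec, options=None,
    *, predict_vcf_path=None, manifest_out=None, **train_kwargs
) -> dict:
    """Train then predict in one step (prediction VCF defaults to the
    training VCF); byte-identical to running the two steps separately."""
    m1 = run_train(vcf_path, pheno_path, weights_out, spec, options, **train_kwargs)
    env_csv = train_kwargs.get("env_csv")
    env_assign = None
    if spec.uses_environment:
        # reuse the phenotype table's env column for the prediction samples
        pt = read_phenotypes(pheno_path)
        env_assign = str(weights_out) + ".env_assign.csv"
        pt.df[["sample", "env"]].to_csv(env_assign, index=False)
    m2 = run_predict(
        predict_vcf_path or vcf_path, weights_out, predictions_out,
        env_csv=env_csv, env_assign_path=env_assign,
    )
    manifest = {"command": "train-predict", "train": m1, "predict": m2}
    if manifest_out is not None:
        with open(manifest_out, "w") as fh:
            json.dump(manifest, fh, indent=1)
    return manifest


def _read_id_list(path) -> list[str]:
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if not ids:
        raise ValueError(f"empty inbred-line id list: {path}")
    return ids


def run_select_parents(
    panel_vcf,
    weights_path,
    predictions_out,
    top5_out,
    *,
    inbred_list_path=None,
    pairs_path=None,
    f1_vcf=None,
    direction: str = "maximize",
    manifest_out=None,
) -> dict:
    """Rank candidate crosses of an inbred panel and write full + top-5 CSVs."""
    try:
        w = load_weights(weights_path)
        panel, _ = read_vcf(panel_vcf)
        panel = impute_missing(panel)
        if inbred_list_path is not None:
            ids = _read_id_list(inbred_list_path)
            pos = {s: i for i, s in enumerate(panel.samples)}
            unknown = [i for i in ids if i not in pos]
            if unknown:
                raise ValueError(f"inbred ids absent from panel VCF: {unknown[:5]}")
            panel = panel.subset_samples([pos[i] for i in ids])
        if pairs_path is not None:
            pairs_df = pd.read_csv(pairs_path, dtype=str)
            pairs_df.columns = [c.strip().lower() for c in pairs_df.columns]
            plan = list(zip(pairs_df["female"], pairs_df["male"]))
        else:
            raise ValueError("a pair list CSV (female,male) is required")
        f1 = None
        if f1_vcf is not None:
            f1, _ = read_vcf(f1_vcf)
            f1 = impute_missing(align_to_locus_map(f1, w.locus_map))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("load-selection-inputs", exc) from exc

    try:
        panel = align_to_locus_map(panel, w.locus_map)
        ranked = select_parents(panel, plan, w, direction, f1=f1)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("select-parents", exc) from exc
    ranked.table.to_csv(predictions_out, index=False)
    ranked.top5.to_csv(top5_out, index=False)
    inputs = {"panel_vcf": panel_vcf, "weights": weights_path, "pairs": pairs_path}
    if inbred_list_path is not None:
        inputs["inbred_list"] = inbred_list_path
    if f1_vcf is not None:
        inputs["f1_vcf"] = f1_vcf
    return _write_manifest(
        manifest_out, "select-parents", inputs,
        {"predictions": predictions_out, "top5": top5_out},
        w.spec.seed, {"direction": direction},
    )


def run_train_select(
    vcf_path, pheno_path, weights_out, panel_vcf, predictions_out, top5_out,
    spec, options=None, *, pairs_path=None, inbred_list_path=None, f1_vcf=None,
    direction: str = "maximize", manifest_out=None, **train_kwargs
) -> dict:
    """Train a model, then rank candidate crosses with it."""
    m1 = run_train(vcf_path, pheno_path, weights_out, spec, options, **train_kwargs)
    m2 = run_select_parents(
        panel_vcf, weights_out, predictions_out, top5_out,
        inbred_list_path=inbred_list_path, pairs_path=pairs_path,
        f1_vcf=f1_vcf, direction=direction,
    )
    manifest = {"command": "train-select", "train": m1, "select": m2}
    if manifest_out is not None:
        with open(manifest_out, "w") as fh:
            json.dump(manifest, fh, indent=1)
    return manifest
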