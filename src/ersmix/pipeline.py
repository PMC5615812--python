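"""End-to-end runner: split, construct each ERS on the training half,
evaluate on the held-out half, and fit endpoint associations.

The workflow mirrors the standard ERS pipeline: log10 transform of
exposures and outcome, a seeded 1:1 train/test split, per-method score
construction on the training half only, three-way evaluation (continuous
fit, AUC for the dichotomized biomarker, quintile OR) on the test half,
and z-scored ERS associations with the binary and survival endpoints.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import aenet, bart, bkmr, superlearner
from .association import cox_age_timescale, fit_endpoint_model
from .core import ERSVector
from .evaluation import (
    auc_with_tests,
    continuous_metrics,
    quintile_risk_stratification,
    standardize_ers,
)
from .io import RunConfig, config_hash, read_cohort, write_table
from .preprocessing import (
    ExpandedDesign,
    Standardizer,
    covariate_design,
    expand_interactions,
    log10_transform,
    residualize,
    split_train_test,
)
from .synthetic import MixtureCohort, SimulationConfig, dichotomize_outcome, simulate_cohort

logger = logging.getLogger("ersmix")

__all__ = ["run_pipeline", "construct_ers", "MethodOutput"]


def _mains_design(E: np.ndarray, names: list[str]) -> ExpandedDesign:
    return ExpandedDesign(
        X=np.asarray(E, float),
        names=list(names),
        index_map={n: {"type": "main", "exposures": (n,)} for n in names},
    )


@dataclass
class MethodOutput:
    method: str
    ers_train: ERSVector
    ers_test: ERSVector
    artifacts: dict  # coefficient / importance / PIP tables


def construct_ers(
    method: str,
    train: MixtureCohort,
    test: MixtureCohort,
    seed: int,
    settings: dict | None = None,
) -> MethodOutput:
    """Fit one engine on the (log10-scale) training cohort, score both halves."""
    settings = dict(settings or {})
    names = train.exposure_names
    E_tr = train.exposures.to_numpy(float)
    E_te = test.exposures.to_numpy(float)
    y_tr = train.outcome.to_numpy(float)
    Z_tr, z_names = covariate_design(train.covariates)
    Z_te, _ = covariate_design(test.covariates)

    scaler = Standardizer().fit(E_tr)
    Es_tr = scaler.transform(E_tr)
    Es_te = scaler.transform(E_te)

    if method in ("AENET-M", "AENET-I"):
        if method == "AENET-I":
            design_tr = expand_interactions(Es_tr, names)
            design_te = expand_interactions(Es_te, names)
        else:
            design_tr = _mains_design(Es_tr, names)
            design_te = _mains_design(Es_te, names)
        terms = z_names + design_tr.names
        X = np.column_stack([Z_tr, design_tr.X])
        free = np.array([True] * len(z_names) + [False] * len(design_tr.names))
        term_types = {t: "covariate" for t in z_names}
        term_types.update({t: design_tr.index_map[t]["type"] for t in design_tr.names})
        fit = aenet.fit_adaptive_elastic_net(
            X,
            y_tr,
            terms=terms,
            term_types=term_types,
            penalty_free=free,
            seed=seed,
            fit_id=f"{method}@{seed}",
            **settings,
        )
        ers_tr = aenet.compute_ers_linear(fit, design_tr)
        ers_te = aenet.compute_ers_linear(fit, design_te)
        ers_tr.method = ers_te.method = method
        return MethodOutput(method, ers_tr, ers_te, {"coefficients": fit.coefficient_table()})

    if method == "BART":
        res = residualize(y_tr, Es_tr, Z_tr, z_names)
        model = bart.fit_bart(
            res.E_star,
            res.Y_star,
            m=settings.pop("m", 200),
            iterations=settings.pop("iterations", 1000),
            burn_in=settings.pop("burn_in", 200),
            seed=seed,
            **settings,
        )
        _, Es_te_star = res.transform(None, Es_te, Z_te)
        ers_tr = ERSVector(model.train_pred_mean, "BART", f"BART@{seed}")
        ers_te = bart.compute_ers_bart(model, Es_te_star, fit_id=f"BART@{seed}")
        importance = pd.DataFrame(
            {"exposure": names, "inclusion_proportion": bart.bart_variable_importance(model)}
        )
        return MethodOutput(method, ers_tr, ers_te, {"importance": importance})

    if method == "BKMR":
        model = bkmr.fit_bkmr(
            Es_tr,
            Z_tr,
            y_tr,
            iterations=settings.pop("iterations", 2000),
            seed=seed,
            z_names=z_names,
            **settings,
        )
        ers_tr = bkmr.compute_ers_bkmr(model, Es_tr, fit_id=f"BKMR@{seed}")
        ers_te = bkmr.compute_ers_bkmr(model, Es_te, fit_id=f"BKMR@{seed}")
        pip = pd.DataFrame({"exposure": names, "pip": model.pip})
        return MethodOutput(method, ers_tr, ers_te, {"pip": pip})

    if method == "SL":
        res = residualize(y_tr, Es_tr, Z_tr, z_names)
        registry = settings.pop("registry", None) or superlearner.default_registry(
            fast=settings.pop("fast", True)
        )
        V = settings.pop("V", 10)
        want_importance = settings.pop("importance", False)
        fit = superlearner.fit_superlearner(
            registry,
            res.E_star,
            res.Y_star,
            V=V,
            seed=seed,
            fit_id=f"SL@{seed}",
        )
        _, Es_te_star = res.transform(None, Es_te, Z_te)
        ers_tr = superlearner.compute_ers_sl(fit, res.E_star)
        ers_te = superlearner.compute_ers_sl(fit, Es_te_star)
        artifacts = {"weights": fit.weight_table()}
        if want_importance:
            # p+1 full SL reruns: off by default for runtime
            imp = superlearner.sl_variable_importance(
                registry, res.E_star, res.Y_star, names, V=V, seed=seed
            )
            artifacts["importance"] = imp.table
        return MethodOutput(method, ers_tr, ers_te, artifacts)

    raise ValueError(f"unknown method: {method!r}")


def _normalize_sim(simulate: dict) -> dict:
    """Coerce YAML-friendly forms: list block specs and 'AxB' string keys."""
    out = dict(simulate)
    if "block_spec" in out:
        out["block_spec"] = [tuple(b) for b in out["block_spec"]]
    if "beta_inter" in out:
        coerced = {}
        for k, v in out["beta_inter"].items():
            if isinstance(k, str):
                a, _, b = k.partition("x")
                if not b:
                    raise ValueError(f"interaction key {k!r} is not of the form 'AxB'")
                coerced[(a, b)] = v
            else:
                coerced[tuple(k)] = v
        out["beta_inter"] = coerced
    if "gm" in out and out["gm"] is not None:
        out["gm"] = tuple(out["gm"])
    if "gsd" in out and out["gsd"] is not None:
        out["gsd"] = tuple(out["gsd"])
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured run; returns the output directory.

    Outputs: per-method coefficient/importance tables, an ERS table
    (subject, split, method, score, z-score), a comparison report (JSON),
    an association table, and a log of seeds and settings.  All numeric
    files carry the run seed and config hash in a header comment and no
    timestamps, so identical configs give byte-identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    header = f"seed={config.seed} config={chash}"

    log_lines = [f"seed={config.seed}", f"config_hash={chash}"]

    if config.input_path is not None:
        cohort = read_cohort(config.input_path, config.schema)
    else:
        sim = SimulationConfig(**{"seed": config.seed, **_normalize_sim(config.simulate)})
        cohort = simulate_cohort(sim)
    log_lines.append(f"n={cohort.n} p={len(cohort.exposure_names)}")

    cohort = log10_transform(cohort)
    train, test = split_train_test(cohort, ratio=config.split_ratio, seed=config.seed)
    log_lines.append(f"split: train={train.n} test={test.n} ratio={config.split_ratio}")

    y_tr = train.outcome.to_numpy(float)
    y_te = test.outcome.to_numpy(float)
    Z_tr, z_names = covariate_design(train.covariates)
    Z_te, _ = covariate_design(test.covariates)
    bin_tr, threshold = dichotomize_outcome(y_tr, 0.9)
    bin_te = (y_te >= threshold).astype(int)
    log_lines.append(f"dichotomization threshold (log10 outcome, train q90): {threshold:.6g}")

    ers_rows = []
    reports = {}
    assoc_rows = []
    failures = []

    for method in config.methods:
        try:
            out = construct_ers(
                method, train, test, seed=config.seed, settings=config.settings.get(method)
            )
        except Exception as exc:  # noqa: BLE001 - record and continue
            logger.error("method %s failed: %s", method, exc)
            failures.append((method, str(exc)))
            log_lines.append(f"FAILED {method}: {exc}")
            continue

        for key, table in out.artifacts.items():
            write_table(table, outdir / f"{key}_{method}.csv", header)

        ers_z_tr = standardize_ers(out.ers_train)
        ers_z_te = standardize_ers(out.ers_test, reference=out.ers_train.values)
        for split, ers, ers_z in (
            ("train", out.ers_train, ers_z_tr),
            ("test", out.ers_test, ers_z_te),
        ):
            for i, (v, z) in enumerate(zip(ers.values, ers_z.values)):
                ers_rows.append(
                    {"subject": i, "split": split, "method": method, "ers": v, "z": z}
                )

        try:
            cm = continuous_metrics(
                y_tr, out.ers_train.values, Z_tr, y_te, out.ers_test.values, Z_te
            )
            auc = auc_with_tests(
                bin_tr,
                Z_tr,
                out.ers_train.values,
                bin_te,
                Z_te,
                out.ers_test.values,
                n_perm=200,
                n_boot=500,
                seed=config.seed,
            )
        except Exception as exc:  # noqa: BLE001 - record and continue
            logger.error("evaluation for %s failed: %s", method, exc)
            failures.append((method, str(exc)))
            log_lines.append(f"FAILED {method} (evaluation): {exc}")
            continue
        # quintile OR: adjusted model first; under quasi-separation (strong
        # score, rare outcome) fall back to the unadjusted cross-product
        # ratio, and if an extreme quintile has no cases at all, report the
        # OR as unavailable rather than an infinite estimate
        quint = None
        quint_adjusted = None
        try:
            quint = quintile_risk_stratification(
                out.ers_train.values, out.ers_test.values, bin_te, Z_te
            )
            quint_adjusted = True
        except (RuntimeError, ValueError, np.linalg.LinAlgError) as exc:
            log_lines.append(f"{method}: adjusted quintile OR unavailable ({exc})")
            try:
                quint = quintile_risk_stratification(
                    out.ers_train.values, out.ers_test.values, bin_te, None
                )
                quint_adjusted = False
            except (RuntimeError, ValueError) as exc2:
                logger.warning("%s: quintile OR undefined: %s", method, exc2)
                log_lines.append(f"{method}: quintile OR undefined ({exc2})")
        reports[method] = {
            **cm,
            **{k: (list(v) if isinstance(v, tuple) else v) for k, v in auc.items()},
            "quintile_or": None if quint is None else quint["or"],
            "quintile_or_ci": None if quint is None else list(quint["ci"]),
            "quintile_cutpoints": None if quint is None else list(quint["cutpoints"]),
            "quintile_adjusted": quint_adjusted,
        }

        if test.binary is not None:
            try:
                res = fit_endpoint_model(
                    ers_z_te.values,
                    test.binary.to_numpy(int),
                    Z_te,
                    "logistic",
                    endpoint_name="binary_endpoint",
                    z_names=z_names,
                )
                assoc_rows.append({"method": method, **res.summary_row()})
            except (RuntimeError, np.linalg.LinAlgError) as exc:
                logger.warning("%s: binary association failed: %s", method, exc)
                log_lines.append(f"{method}: binary association unavailable ({exc})")
        if test.survival is not None:
            # age enters through the time scale only
            z_no_age = [n for n in z_names if n != "age"]
            idx = [z_names.index(n) for n in z_no_age]
            try:
                res = cox_age_timescale(
                    ers_z_te.values,
                    test.survival["entry_age"].to_numpy(float),
                    test.survival["exit_age"].to_numpy(float),
                    test.survival["event"].to_numpy(int),
                    Z_te[:, idx] if idx else None,
                    endpoint_name="mortality",
                    z_names=z_no_age,
                )
                assoc_rows.append({"method": method, **res.summary_row()})
            except Exception as exc:  # noqa: BLE001 - endpoint isolation
                logger.warning("%s: Cox association failed: %s", method, exc)
                log_lines.append(f"{method}: Cox association unavailable ({exc})")
        log_lines.append(f"done {method}")

    if ers_rows:
        write_table(pd.DataFrame(ers_rows), outdir / "ers.csv", header)
    report_obj = {"seed": config.seed, "config": chash, "methods": reports}
    (outdir / "report.json").write_text(json.dumps(report_obj, indent=1, sort_keys=True))
    if assoc_rows:
        write_table(pd.DataFrame(assoc_rows), outdir / "associations.csv", header)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")

    if failures and len(failures) == len(config.methods):
        raise RuntimeError(f"all methods failed: {failures}")
    if failures:
        raise RuntimeError(
            f"partial failure (outputs retained for completed methods): {failures}"
        )
    return outdir
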