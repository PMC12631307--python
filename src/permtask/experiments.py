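"""Reproducible validation experiments on synthetic study conditions.

Each function sets up one of the toolkit's headline checks — split hygiene,
noise-model parameter recovery, planted-outlier recall, coverage
reproduction, cross-task learning, descriptor augmentation, the late-assay
temporal signature — generates the data it needs from
:mod:`permtask.synthetic`, runs the pipeline, and returns plain numbers.
They are used both by the test suite and by the acceptance script, so the
measured quantities come from one code path.

Problem sizes are desk scale: 2000 compounds for modeling experiments,
5000 replicate groups for parameter recovery, 10000 compounds for the
coverage check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .curation import ENDPOINTS, aggregate, coverage_summary, curate, fit_sigma_model
from .modeling import MultitaskRegressor, fit_stl_baseline, rmse, spearman_rho
from .splitting import (
    bemis_murcko_scaffold,
    leakage_report,
    scaffold_balanced_split,
    temporal_rounds,
)
from .synthetic import GeneratorConfig, generate


def _curated(n_compounds: int, seed: int, **config_kwargs):
    config = GeneratorConfig(n_compounds=n_compounds, seed=seed, **config_kwargs)
    dataset = generate(config)
    # the library is already canonical; skip re-standardization for speed
    result = curate(dataset.measurements, standardize=False)
    return dataset, result


# ---------------------------------------------------------------------------
# split hygiene


def split_hygiene(n_compounds: int = 2000, seeds=(0, 1, 2, 3, 4)) -> dict:
    """Scaffold/temporal split invariants over several generator seeds.

    Returns the maximum violation counts across seeds: shared scaffolds
    between train and test, shared SMILES in all-for-one splits, per-endpoint
    record overlap in leaky splits, broken nesting or time ordering, plus the
    largest all-for-one leakage percentage (exactly 0 when clean).
    """
    out = {
        "scaffold_overlap_max": 0,
        "afo_smiles_overlap_max": 0,
        "afo_leakage_pct_max": 0.0,
        "leaky_record_overlap_max": 0,
        "nesting_violations": 0,
        "time_order_violations": 0,
    }
    for seed in seeds:
        _, res = _curated(n_compounds, seed)
        table = res.table

        plan = scaffold_balanced_split(table, n_repeats=1, seed=seed)
        for rnd in plan.rounds:
            tr = {bemis_murcko_scaffold(s) for s, _ in rnd.train}
            te = {bemis_murcko_scaffold(s) for s, _ in rnd.test}
            out["scaffold_overlap_max"] = max(out["scaffold_overlap_max"], len(tr & te))

        leaky = temporal_rounds(table, 5, mode="leaky")
        stamps = table.timestamps
        prev_train: frozenset = frozenset()
        for rnd in leaky.rounds:
            out["leaky_record_overlap_max"] = max(
                out["leaky_record_overlap_max"], len(rnd.train & rnd.test)
            )
            if not prev_train <= rnd.train:
                out["nesting_violations"] += 1
            prev_train = rnd.train
            if rnd.train and rnd.test:
                max_train = max(stamps.at[s, e] for s, e in rnd.train)
                min_test = min(stamps.at[s, e] for s, e in rnd.test)
                if max_train > min_test:
                    out["time_order_violations"] += 1

        afo = temporal_rounds(table, 5, mode="all_for_one")
        for rnd in afo.rounds:
            shared = {s for s, _ in rnd.train} & {s for s, _ in rnd.test}
            out["afo_smiles_overlap_max"] = max(out["afo_smiles_overlap_max"], len(shared))
        rep = leakage_report(afo, table).to_frame()
        out["afo_leakage_pct_max"] = max(
            out["afo_leakage_pct_max"], float(rep.train_overlap_pct.max())
        )
    return out


# ---------------------------------------------------------------------------
# noise-model parameter recovery and planted outliers


def sigma_slope_recovery(
    endpoint: str = "Caco2Papp", n_groups: int = 5000, seed: int = 0
) -> dict:
    """Recover the generator's heteroscedastic noise slope from sample SDs.

    Generates enough compounds for ~``n_groups`` replicate groups on the
    target endpoint (every group replicated, censoring off so the recovery
    is a pure regression question), then fits the SD-vs-mean OLS.
    """
    # each endpoint carries ~37% of compounds at the default coverage pattern
    n_compounds = int(np.ceil(n_groups / 0.37))
    config = GeneratorConfig(
        n_compounds=n_compounds,
        seed=seed,
        replicate_rate=1.0,
        censor_limits={e: None for e in ENDPOINTS},
    )
    dataset = generate(config)
    records = aggregate(dataset.measurements)
    model = fit_sigma_model(records, endpoint)
    true_slope = config.noise_slope[endpoint]
    return {
        "true_slope": true_slope,
        "fitted_slope": model.slope,
        "relative_error": abs(model.slope - true_slope) / abs(true_slope),
        "n_groups": model.n_fit,
    }


def planted_outlier_recovery(
    n_compounds: int = 2000, outlier_frac: float = 0.05, seed: int = 0
) -> dict:
    """Recall/precision of the 2-sigma rule on 5x-inflated replicate groups."""
    config = GeneratorConfig(
        n_compounds=n_compounds, seed=seed, outlier_frac=outlier_frac,
        outlier_inflation=5.0,
    )
    dataset = generate(config)
    result = curate(dataset.measurements, standardize=False, sigma_k=2.0)
    planted = dataset.outlier_cells
    hits = planted & result.outliers
    return {
        "n_planted": len(planted),
        "recall": len(hits) / len(planted) if planted else float("nan"),
        "precision": len(hits) / len(result.outliers) if result.outliers else float("nan"),
    }


# ---------------------------------------------------------------------------
# coverage


def coverage_reproduction(n_compounds: int = 10_000, seed: int = 0) -> dict:
    """Endpoint-count fractions of a generated dataset vs the target pattern.

    Measured on the aggregated table before outlier removal: the coverage
    pattern is a generator property, and the noise-model filter would
    otherwise shift a small fraction of compounds toward fewer endpoints.
    """
    from .curation import aggregate, build_multitask_table

    dataset = generate(GeneratorConfig(n_compounds=n_compounds, seed=seed))
    table = build_multitask_table(aggregate(dataset.measurements))
    fractions = coverage_summary(table)
    target = dict(zip((1, 2, 3, 4), GeneratorConfig().coverage_probs))
    return {
        "fractions": fractions,
        "target": target,
        "max_abs_error": max(abs(fractions[k] - target[k]) for k in target),
    }


# ---------------------------------------------------------------------------
# cross-learning, zero-shot and augmentation


def cross_learning_run(
    sparse_endpoint: str = "MDCKER",
    n_sparse_train: int = 150,
    n_compounds: int = 2000,
    seed: int = 0,
    include_rf_baseline: bool = False,
) -> dict:
    """Multitask vs single-task RMSE on an endpoint with few training labels.

    All other endpoints keep their full training data (leaky, compound-level
    sharing allowed) so the multitask net can cross-learn.  The single-task
    comparator is the *same network* trained only on the sparse endpoint's
    labels, isolating the effect of the shared representation; the
    random-forest baseline can be reported alongside.
    """
    dataset, result = _curated(n_compounds, seed)
    table = result.table
    rng = np.random.default_rng(seed)
    ep_smiles = sorted(s for s, e in table.observed_cells() if e == sparse_endpoint)
    train_ep = set(rng.choice(ep_smiles, size=n_sparse_train, replace=False))
    test_ep = [s for s in ep_smiles if s not in train_ep]
    cells = table.observed_cells()
    train_cells = {(s, e) for s, e in cells if e != sparse_endpoint or s in train_ep}
    stl_cells = {(s, sparse_endpoint) for s in train_ep}

    obs = table.values.loc[test_ep, sparse_endpoint].to_numpy()
    mtl = MultitaskRegressor(table, train_cells=train_cells).fit(seed=seed)
    rmse_mtl = rmse(mtl.predict(test_ep)[sparse_endpoint].to_numpy(), obs)
    stl = MultitaskRegressor(table, train_cells=stl_cells).fit(seed=seed)
    rmse_stl = rmse(stl.predict(test_ep)[sparse_endpoint].to_numpy(), obs)
    out = {"rmse_mtl": rmse_mtl, "rmse_stl": rmse_stl, "n_test": len(test_ep)}
    if include_rf_baseline:
        rf = fit_stl_baseline(table, sparse_endpoint, train_cells=train_cells, seed=seed)
        out["rmse_rf_baseline"] = rmse(rf.predict(test_ep), obs)
    return out


def zero_shot_run(
    endpoint: str = "NIHMDCKER", round_index: int = 1, n_compounds: int = 2000,
    seed: int = 0,
) -> dict:
    """Rank correlation vs truth for an endpoint absent from temporal training.

    Early temporal rounds contain no labels for the late-start endpoint, so
    its predictions rely entirely on cross-task transfer through the shared
    readout.
    """
    dataset, result = _curated(n_compounds, seed)
    table = result.table
    plan = temporal_rounds(table, 5, mode="leaky")
    rnd = plan.rounds[round_index]
    n_train_ep = sum(1 for _, e in rnd.train if e == endpoint)
    test_smiles = sorted(s for s, e in rnd.test if e == endpoint)
    fitted = MultitaskRegressor(table, train_cells=set(rnd.train)).fit(seed=seed)
    pred = fitted.predict(test_smiles)[endpoint].to_numpy()
    truth = dataset.truth.loc[test_smiles, endpoint].to_numpy()
    return {
        "rho_vs_truth": spearman_rho(pred, truth),
        "n_train_endpoint": n_train_ep,
        "n_test": len(test_smiles),
    }


def augmentation_run(
    n_compounds: int = 2000, test_frac: float = 0.2, seed: int = 0,
    extra: str = "plusplus",
) -> dict:
    """Descriptor-augmented vs plain multitask RMSE on a held-out fifth."""
    dataset, result = _curated(n_compounds, seed)
    table = result.table
    rng = np.random.default_rng(seed)
    smiles = table.smiles
    test = set(rng.choice(smiles, size=int(round(test_frac * len(smiles))), replace=False))
    cells = table.observed_cells()
    train_cells = {c for c in cells if c[0] not in test}
    test_cells = sorted(c for c in cells if c[0] in test)
    obs = [table.values.at[s, e] for s, e in test_cells]

    def score(extra_features):
        fitted = MultitaskRegressor(
            table, train_cells=train_cells, extra_features=extra_features
        ).fit(seed=seed)
        frame = fitted.predict(sorted(test))
        return rmse([frame.at[s, e] for s, e in test_cells], obs)

    return {"rmse_plain": score(None), "rmse_augmented": score(extra)}


# ---------------------------------------------------------------------------
# late-assay temporal signature


def late_endpoint_signature(n_compounds: int = 2000, seed: int = 0) -> pd.Series:
    """Per-round test-set percentage of the late-start endpoint (leaky split)."""
    dataset, result = _curated(n_compounds, seed)
    plan = temporal_rounds(result.table, 5, mode="leaky")
    rep = leakage_report(plan, result.table).to_frame()
    late = dataset.config.late_endpoint
    series = (
        rep[rep.endpoint == late].set_index("round").test_pct.sort_index()
    )
    return series
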