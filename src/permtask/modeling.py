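"""Single-task baselines and the masked-loss multitask regressor.

The central object is :class:`MultitaskRegressor`, a model built from a
:class:`~permtask.curation.MultitaskTable` (optionally restricted to a set of
training cells) whose :meth:`~MultitaskRegressor.fit` returns a
:class:`MultitaskResults` carrying the fitted network, per-task target
statistics, training history and a ``summary()`` table.  The molecular
encoder is pluggable; the reference implementation is hashed circular
(Morgan) fingerprints, optionally concatenated with a descriptor block before
the feed-forward head — the descriptor-augmented variants mirror the
"+"/"++" model flavours.

Training minimizes a masked squared loss: unobserved cells of the sparse
endpoint matrix contribute nothing, so one network learns from whatever
labels each compound has.  Targets are standardized per task and the
transform inverted at prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from ._mlp import MaskedMLP, masked_mse
from .curation import ENDPOINTS, MultitaskTable
from .descriptors import compute_descriptors
from .splitting import SplitPlan, leakage_report

logger = logging.getLogger(__name__)

Cell = tuple[str, str]

masked_loss = masked_mse


# ---------------------------------------------------------------------------
# metrics


def rmse(pred, obs) -> float:
    """Root mean squared error."""
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("pred and obs must be equal-length and non-empty")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def spearman_rho(pred, obs) -> float | None:
    """Spearman rank correlation with average-rank ties; None if degenerate."""
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.size < 3:
        raise ValueError("need at least 3 pairs for a rank correlation")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        logger.warning("constant vector; Spearman rho undefined")
        return None
    return float(stats.spearmanr(pred, obs).statistic)


# ---------------------------------------------------------------------------
# featurization


class MorganEncoder:
    """Hashed circular-fingerprint encoder (radius 2 by default)."""

    def __init__(self, n_bits: int = 512, radius: int = 2):
        self.n_bits, self.radius = n_bits, radius
        self._gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
        self._cache: dict[str, np.ndarray] = {}

    def __call__(self, smiles: list[str]) -> np.ndarray:
        out = np.zeros((len(smiles), self.n_bits), np.float32)
        for i, s in enumerate(smiles):
            fp = self._cache.get(s)
            if fp is None:
                mol = Chem.MolFromSmiles(s)
                if mol is None:
                    raise ValueError(f"invalid SMILES: {s!r}")
                fp = np.zeros(self.n_bits, np.float32)
                on = self._gen.GetFingerprint(mol).GetOnBits()
                fp[list(on)] = 1.0
                self._cache[s] = fp
            out[i] = fp
        return out


@dataclass
class _FeaturePipeline:
    """Fingerprints + imputed, standardized descriptors (train statistics only)."""

    encoder: MorganEncoder
    descriptors: pd.DataFrame | None = None
    medians: pd.Series | None = None
    means: pd.Series | None = None
    sds: pd.Series | None = None

    def fit(self, train_smiles: list[str]) -> "_FeaturePipeline":
        if self.descriptors is not None:
            block = self.descriptors.loc[train_smiles]
            self.medians = block.median()
            filled = block.fillna(self.medians).fillna(0.0)
            self.means = filled.mean()
            self.sds = filled.std().replace(0.0, 1.0).fillna(1.0)
        return self

    def transform(self, smiles: list[str]) -> np.ndarray:
        X = self.encoder(smiles)
        if self.descriptors is None:
            return X
        block = self.descriptors.reindex(smiles)
        block = block.fillna(self.medians).fillna(0.0)
        Z = ((block - self.means) / self.sds).to_numpy(np.float32)
        return np.hstack([X, Z])


# ---------------------------------------------------------------------------
# multitask model (model / results pair)


class MultitaskRegressor:
    """Masked-loss multitask network over a sparse endpoint table.

    Parameters
    ----------
    table : MultitaskTable
        The curated compounds x endpoints table.
    train_cells : set of (smiles, endpoint), optional
        Restrict training to these observed cells (default: all observed).
    extra_features : DataFrame or {"plus","plusplus"}, optional
        Descriptor block concatenated to the fingerprint encoding.
    """

    def __init__(
        self,
        table: MultitaskTable,
        train_cells: set[Cell] | None = None,
        extra_features: pd.DataFrame | str | None = None,
        n_bits: int = 512,
        radius: int = 2,
        hidden: tuple[int, int] = (128, 64),
        lr: float = 1e-3,
        l2: float = 1e-5,
        l2_task: float = 1e-3,
        max_epochs: int = 200,
        batch_size: int = 256,
        patience: int = 20,
        val_frac: float = 0.1,
    ):
        self.table = table
        self.train_cells = set(train_cells) if train_cells is not None else table.observed_cells()
        bad = self.train_cells - table.observed_cells()
        if bad:
            raise ValueError(f"train cells not observed in the table: {sorted(bad)[:5]}")
        if isinstance(extra_features, str):
            extra_features = compute_descriptors(table.smiles, which=extra_features)
        self.extra_features = extra_features
        self.config = dict(
            n_bits=n_bits, radius=radius, hidden=tuple(hidden), lr=lr, l2=l2,
            l2_task=l2_task, max_epochs=max_epochs, batch_size=batch_size,
            patience=patience, val_frac=val_frac,
        )
        n_endpoints = len({e for _, e in self.train_cells})
        if n_endpoints < 2:
            logger.warning(
                "training data covers %d endpoint(s); multitask model degenerates "
                "to single-task", n_endpoints,
            )

    def _target_matrices(self, smiles: list[str]) -> tuple[np.ndarray, np.ndarray]:
        Y = np.zeros((len(smiles), len(ENDPOINTS)), np.float32)
        M = np.zeros_like(Y)
        pos = {s: i for i, s in enumerate(smiles)}
        for s, e in self.train_cells:
            if s in pos:
                j = ENDPOINTS.index(e)
                Y[pos[s], j] = self.table.values.at[s, e]
                M[pos[s], j] = 1.0
        return Y, M

    def fit(self, seed: int = 0) -> "MultitaskResults":
        cfg = self.config
        train_smiles = sorted({s for s, _ in self.train_cells})
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(train_smiles))
        n_val = max(1, int(round(cfg["val_frac"] * len(train_smiles)))) if len(train_smiles) > 10 else 0
        val_smiles = [train_smiles[i] for i in perm[:n_val]]
        fit_smiles = [train_smiles[i] for i in perm[n_val:]]

        pipeline = _FeaturePipeline(
            MorganEncoder(cfg["n_bits"], cfg["radius"]), self.extra_features
        ).fit(fit_smiles)
        X = pipeline.transform(fit_smiles)
        Y, M = self._target_matrices(fit_smiles)

        # per-task standardization from training cells; pooled fallback for
        # tasks with no labels (their scale is unidentified without data)
        obs_vals = Y[M > 0]
        pooled_mu = float(obs_vals.mean()) if obs_vals.size else 0.0
        pooled_sd = float(obs_vals.std()) if obs_vals.size > 1 else 1.0
        pooled_sd = pooled_sd if pooled_sd > 0 else 1.0
        mu = np.full(len(ENDPOINTS), pooled_mu, np.float32)
        sd = np.full(len(ENDPOINTS), pooled_sd, np.float32)
        for j in range(len(ENDPOINTS)):
            col = Y[:, j][M[:, j] > 0]
            if col.size >= 2 and col.std() > 0:
                mu[j], sd[j] = col.mean(), col.std()
            elif col.size >= 1:
                mu[j] = col.mean()
        Ys = np.where(M > 0, (Y - mu) / sd, 0.0).astype(np.float32)

        if val_smiles:
            Xv = pipeline.transform(val_smiles)
            Yv, Mv = self._target_matrices(val_smiles)
            Yvs = np.where(Mv > 0, (Yv - mu) / sd, 0.0).astype(np.float32)
        else:
            Xv = Yvs = Mv = None

        net = MaskedMLP(
            n_features=X.shape[1], n_tasks=len(ENDPOINTS), hidden=cfg["hidden"],
            l2=cfg["l2"], l2_task=cfg["l2_task"], lr=cfg["lr"],
            seed=int(rng.integers(2**31 - 1)),
        )
        history = net.fit(
            X, Ys, M, Xv, Yvs, Mv,
            max_epochs=cfg["max_epochs"], batch_size=cfg["batch_size"],
            patience=cfg["patience"], seed=int(rng.integers(2**31 - 1)),
        )
        return MultitaskResults(
            model=self, net=net, pipeline=pipeline, task_mean=mu, task_sd=sd,
            history=history, seed=seed,
            n_train={e: int(sum(1 for s, e2 in self.train_cells if e2 == e)) for e in ENDPOINTS},
        )


@dataclass
class MultitaskResults:
    """Fitted multitask regressor: predictions, scales and diagnostics."""

    model: MultitaskRegressor
    net: MaskedMLP
    pipeline: _FeaturePipeline
    task_mean: np.ndarray
    task_sd: np.ndarray
    history: dict
    seed: int
    n_train: dict[str, int] = field(default_factory=dict)

    def predict(self, smiles: list[str]) -> pd.DataFrame:
        """Predicted log10 values for all four endpoints, released-model order."""
        X = self.pipeline.transform(list(smiles))
        raw = self.net.forward(X)
        out = raw * self.task_sd + self.task_mean
        return pd.DataFrame(out, index=pd.Index(smiles, name="smiles"), columns=list(ENDPOINTS))

    def summary(self) -> str:
        lines = [
            "Masked multitask regressor",
            "=" * 54,
            f"{'endpoint':<12}{'n_train':>9}{'mean':>9}{'sd':>8}",
            "-" * 54,
        ]
        for j, e in enumerate(ENDPOINTS):
            lines.append(
                f"{e:<12}{self.n_train.get(e, 0):>9}"
                f"{self.task_mean[j]:>9.3f}{self.task_sd[j]:>8.3f}"
            )
        lines.append("-" * 54)
        lines.append(
            f"stopped at epoch {self.history.get('best_epoch')} | "
            f"final train loss {self.history['train'][-1]:.4f}"
            + (
                f" | val loss {min(self.history['val']):.4f}"
                if self.history.get("val")
                else ""
            )
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# single-task baseline


@dataclass
class STLBaselineResults:
    """Fitted per-endpoint random-forest baseline."""

    endpoint: str
    forest: RandomForestRegressor
    feature_names: list[str]
    medians: pd.Series
    descriptors: pd.DataFrame
    train_smiles: list[str]
    train_y: np.ndarray
    seed: int

    def _features(self, smiles: list[str]) -> np.ndarray:
        block = self.descriptors.reindex(smiles)[self.feature_names]
        return block.fillna(self.medians).fillna(0.0).to_numpy(float)

    def predict(self, smiles: list[str]) -> np.ndarray:
        return self.forest.predict(self._features(smiles))


def fit_stl_baseline(
    table: MultitaskTable,
    endpoint: str,
    descriptors: pd.DataFrame | None = None,
    train_cells: set[Cell] | None = None,
    seed: int = 0,
    n_estimators: int = 500,
) -> STLBaselineResults:
    """Random-forest regressor on one endpoint only (no cross-learning).

    Degenerate descriptor columns (constant or entirely missing on the
    training set) are dropped; missing values are imputed with training-set
    medians.
    """
    cells = train_cells if train_cells is not None else table.observed_cells()
    smiles = sorted({s for s, e in cells if e == endpoint})
    if len(smiles) < 20:
        raise ValueError(
            f"{endpoint}: need >= 20 training records for the baseline, got {len(smiles)}"
        )
    if descriptors is None:
        descriptors = compute_descriptors(table.smiles, which="baseline_full")
    block = descriptors.loc[smiles]
    keep = [
        c for c in block.columns
        if block[c].notna().any() and np.isfinite(block[c].dropna()).all()
        and block[c].nunique(dropna=True) > 1
    ]
    medians = block[keep].median()
    X = block[keep].fillna(medians).to_numpy(float)
    y = table.values.loc[smiles, endpoint].to_numpy(float)
    forest = RandomForestRegressor(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    ).fit(X, y)
    return STLBaselineResults(
        endpoint=endpoint, forest=forest, feature_names=keep, medians=medians,
        descriptors=descriptors, train_smiles=smiles, train_y=y, seed=seed,
    )


def rank_descriptors(
    baseline: STLBaselineResults, top_k: int = 5, seed: int = 0, n_repeats: int = 5
) -> list[str]:
    """Rank descriptors by mean absolute permutation attribution.

    Shuffling a column that the forest relies on degrades its fit; the mean
    absolute degradation over repeats is the attribution score.  A ``top_k``
    larger than the number of descriptors returns the full ranking.
    """
    X = baseline._features(baseline.train_smiles)
    imp = permutation_importance(
        baseline.forest, X, baseline.train_y, n_repeats=n_repeats, random_state=seed
    )
    order = np.argsort(-np.abs(imp.importances_mean))
    names = [baseline.feature_names[i] for i in order]
    return names[: min(top_k, len(names))]


# ---------------------------------------------------------------------------
# benchmarking


MODEL_NAMES = ("stl", "mtl", "mtl+", "mtl++")


def _fit_predict(
    name: str,
    table: MultitaskTable,
    train_cells: set[Cell],
    test_cells: set[Cell],
    descriptors: dict[str, pd.DataFrame],
    seed: int,
) -> dict[Cell, float]:
    """Fit one model flavour on the train cells, predict the test cells."""
    preds: dict[Cell, float] = {}
    if name == "stl":
        for ep in ENDPOINTS:
            test_smiles = sorted({s for s, e in test_cells if e == ep})
            if not test_smiles:
                continue
            try:
                res = fit_stl_baseline(
                    table, ep, descriptors=descriptors.get("baseline_full"),
                    train_cells=train_cells, seed=seed,
                )
            except ValueError as exc:
                logger.warning("stl %s: %s", ep, exc)
                continue
            for s, v in zip(test_smiles, res.predict(test_smiles)):
                preds[(s, ep)] = float(v)
        return preds

    extra = {"mtl": None, "mtl+": descriptors.get("plus"), "mtl++": descriptors.get("plusplus")}[name]
    res = MultitaskRegressor(table, train_cells=train_cells, extra_features=extra).fit(seed=seed)
    test_smiles = sorted({s for s, _ in test_cells})
    frame = res.predict(test_smiles)
    for s, ep in test_cells:
        preds[(s, ep)] = float(frame.at[s, ep])
    return preds


def benchmark(
    table: MultitaskTable,
    plans: list[SplitPlan],
    models: list[str] = ("stl", "mtl"),
    seed: int = 0,
    attach_leakage: bool = True,
) -> pd.DataFrame:
    """RMSE per (model, strategy, endpoint, round) across split plans.

    One row per cell of the evaluation grid; aggregate with
    :func:`summarize_benchmark` for the mean +/- SD report.  A model failure
    on one round is recorded as a missing RMSE and the run continues.
    """
    for name in models:
        if name not in MODEL_NAMES:
            raise ValueError(f"unknown model {name!r}; known: {MODEL_NAMES}")
    descriptors = {}
    if "stl" in models:
        descriptors["baseline_full"] = compute_descriptors(table.smiles, "baseline_full")
    if "mtl+" in models:
        descriptors["plus"] = compute_descriptors(table.smiles, "plus")
    if "mtl++" in models:
        descriptors["plusplus"] = compute_descriptors(table.smiles, "plusplus")

    rows = []
    for plan in plans:
        leak = leakage_report(plan, table).to_frame() if attach_leakage else None
        for rnd in plan.rounds:
            for name in models:
                try:
                    preds = _fit_predict(
                        name, table, set(rnd.train), set(rnd.test), descriptors, seed
                    )
                except Exception as exc:
                    logger.warning(
                        "%s failed on %s round %d: %s", name, plan.strategy, rnd.round_id, exc
                    )
                    preds = None
                for ep in ENDPOINTS:
                    cells = sorted({(s, e) for s, e in rnd.test if e == ep})
                    if not cells:
                        continue
                    row = {
                        "model": name, "strategy": plan.strategy, "endpoint": ep,
                        "round": rnd.round_id, "n_test": len(cells), "seed": seed,
                        "rmse": np.nan,
                    }
                    if preds is not None:
                        have = [c for c in cells if c in preds]
                        if have:
                            obs = [table.values.at[s, e] for s, e in have]
                            row["rmse"] = rmse([preds[c] for c in have], obs)
                            row["n_test"] = len(have)
                    if leak is not None:
                        m = leak[(leak.endpoint == ep) & (leak["round"] == rnd.round_id)]
                        if len(m):
                            row["test_pct"] = float(m.test_pct.iloc[0])
                            row["train_overlap_pct"] = float(m.train_overlap_pct.iloc[0])
                    rows.append(row)
    return pd.DataFrame(rows)


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of RMSE across rounds, per (model, strategy, endpoint)."""
    return (
        results.groupby(["model", "strategy", "endpoint"])
        .agg(rmse_mean=("rmse", "mean"), rmse_sd=("rmse", "std"), n_rounds=("rmse", "count"))
        .reset_index()
    )
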