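"""Train/test splitting strategies and leakage quantification.

Multitask tables blur the usual notion of a train/test split: a compound can
carry labels for several endpoints, measured years apart.  This module
implements five strategies at the granularity the question demands —

* ``stratified_random_split`` / ``kfold_cv`` / ``modality_folds`` move whole
  compounds (all endpoint cells together);
* ``temporal_rounds`` orders individual (compound, endpoint) records by
  acquisition date and either tolerates cross-endpoint compound sharing
  ("leaky") or excludes any test compound from training entirely
  ("all-for-one");
* ``scaffold_balanced_split`` keeps Bemis-Murcko scaffold groups intact so the
  test set probes unseen chemotypes —

and quantifies the residual compound overlap per endpoint in a
:class:`LeakageReport`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .curation import ENDPOINTS, MultitaskTable

logger = logging.getLogger(__name__)

Cell = tuple[str, str]  # (smiles_std, endpoint)


@dataclass(frozen=True)
class Round:
    round_id: int
    train: frozenset[Cell]
    test: frozenset[Cell]


@dataclass
class SplitPlan:
    """Assignment of every (compound, endpoint) record to train/test per round."""

    strategy: str
    rounds: list[Round]
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for r in self.rounds:
            clash = r.train & r.test
            if clash:
                raise ValueError(f"round {r.round_id}: cells in both train and test: {clash}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.rounds:
            rows += [(s, e, r.round_id, "train") for s, e in sorted(r.train)]
            rows += [(s, e, r.round_id, "test") for s, e in sorted(r.test)]
        return pd.DataFrame(rows, columns=["smiles_std", "endpoint", "round", "role"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, strategy: str = "unknown") -> "SplitPlan":
        rounds = []
        for rid, grp in frame.groupby("round"):
            train = frozenset(
                (r.smiles_std, r.endpoint) for r in grp[grp.role == "train"].itertuples()
            )
            test = frozenset(
                (r.smiles_std, r.endpoint) for r in grp[grp.role == "test"].itertuples()
            )
            rounds.append(Round(int(rid), train, test))
        return cls(strategy=strategy, rounds=sorted(rounds, key=lambda r: r.round_id))


@dataclass
class LeakageReport:
    """Per (endpoint, round) test-set share and train-compound overlap.

    ``test_pct`` — share of the endpoint's records that sit in the test set.
    ``train_overlap_pct`` — share of the endpoint's test compounds whose
    SMILES also appears anywhere (any endpoint) in the training set.
    """

    frame: pd.DataFrame  # columns: endpoint, round, test_pct, train_overlap_pct

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def pivot(self, column: str = "test_pct") -> pd.DataFrame:
        return self.frame.pivot(index="round", columns="endpoint", values=column)


# ---------------------------------------------------------------------------
# scaffolds


def bemis_murcko_scaffold(smiles_std: str) -> str:
    """Canonical Bemis-Murcko framework (ring systems + linkers).

    Acyclic molecules map to the empty string.
    """
    mol = Chem.MolFromSmiles(smiles_std)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles_std!r}")
    core = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(core) if core is not None else ""


def scaffold_groups(smiles: list[str]) -> dict[str, list[str]]:
    """Partition compounds by scaffold; acyclic molecules share one group."""
    groups: dict[str, list[str]] = {}
    for s in smiles:
        groups.setdefault(bemis_murcko_scaffold(s), []).append(s)
    return groups


# ---------------------------------------------------------------------------
# compound-level strategies


def _cells_for(table: MultitaskTable, compounds) -> frozenset[Cell]:
    cells = table.observed_cells()
    comp = set(compounds)
    return frozenset(c for c in cells if c[0] in comp)


def stratified_random_split(
    table: MultitaskTable,
    test_frac: float = 0.2,
    n_repeats: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Repeated-holdout random split stratified by endpoint-availability pattern.

    Strata are the non-empty subsets of endpoints a compound is measured on,
    so the per-endpoint share of the test set stays close to ``test_frac``.
    Compounds move whole: all their endpoint cells share a role.
    """
    if len(table) == 0:
        raise ValueError("empty table")
    patterns = table.mask.apply(lambda row: tuple(row[list(ENDPOINTS)]), axis=1)
    strata: dict[tuple, list[str]] = {}
    for smi, pat in patterns.items():
        strata.setdefault(pat, []).append(smi)

    rounds = []
    for rep in range(n_repeats):
        rng = np.random.default_rng([seed, rep])
        test_compounds: list[str] = []
        for pat in sorted(strata):
            members = sorted(strata[pat])
            n_test = int(round(test_frac * len(members)))
            if len(members) < 1 / test_frac:
                logger.warning(
                    "stratum %s has only %d compounds; best-effort assignment",
                    pat, len(members),
                )
            perm = rng.permutation(len(members))
            test_compounds += [members[i] for i in perm[:n_test]]
        train_compounds = set(table.smiles) - set(test_compounds)
        rounds.append(
            Round(rep + 1, _cells_for(table, train_compounds), _cells_for(table, test_compounds))
        )
    return SplitPlan(
        "stratified_random", rounds, seed=seed,
        params={"test_frac": test_frac, "n_repeats": n_repeats},
    )


def scaffold_balanced_split(
    table: MultitaskTable,
    test_frac: float = 0.2,
    n_repeats: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Greedy scaffold-group assignment toward an 80:20 compound balance.

    Whole Bemis-Murcko scaffold groups are assigned to the split with the
    largest remaining deficit relative to its target size, so train and test
    never share a scaffold.  Groups are visited by descending size; ties in
    size are shuffled per repeat under the seed (ties in deficit go to train).
    """
    smiles = table.smiles
    groups = scaffold_groups(smiles)
    n = len(smiles)
    target_test = test_frac * n
    target_train = (1 - test_frac) * n

    rounds = []
    for rep in range(n_repeats):
        rng = np.random.default_rng([seed, rep])
        keys = sorted(groups, key=lambda k: (-len(groups[k]), k))
        # shuffle within blocks of equal size so repeats differ
        by_size: dict[int, list[str]] = {}
        for k in keys:
            by_size.setdefault(len(groups[k]), []).append(k)
        ordered: list[str] = []
        for size in sorted(by_size, reverse=True):
            block = by_size[size]
            ordered += [block[i] for i in rng.permutation(len(block))]

        train: list[str] = []
        test: list[str] = []
        for k in ordered:
            grp = groups[k]
            deficit_train = target_train - len(train)
            deficit_test = target_test - len(test)
            if len(grp) > target_train:
                logger.warning("scaffold group of size %d exceeds training target", len(grp))
            if deficit_test > deficit_train:
                test += grp
            else:
                train += grp
        if not test:
            logger.warning("scaffold split produced an empty test set")
        rounds.append(Round(rep + 1, _cells_for(table, train), _cells_for(table, test)))
    return SplitPlan(
        "scaffold_balanced", rounds, seed=seed,
        params={"test_frac": test_frac, "n_repeats": n_repeats},
    )


def kfold_cv(table: MultitaskTable, k: int = 5, seed: int = 0) -> SplitPlan:
    """Compound-level k-fold cross-validation; each fold serves once as test."""
    smiles = sorted(table.smiles)
    if k > len(smiles):
        raise ValueError(f"k={k} exceeds number of compounds ({len(smiles)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(smiles))
    folds = np.array_split(perm, k)
    rounds = []
    for i, fold in enumerate(folds):
        test = [smiles[j] for j in fold]
        train = set(smiles) - set(test)
        rounds.append(Round(i + 1, _cells_for(table, train), _cells_for(table, test)))
    return SplitPlan("kfold_cv", rounds, seed=seed, params={"k": k})


def modality_folds(
    table: MultitaskTable, k: int = 5, seed: int = 0
) -> tuple[SplitPlan, pd.DataFrame]:
    """k-fold CV whose evaluation is keyed by (endpoint, modality).

    Returns the fold plan plus a table of evaluation groups with their test
    sizes; groups with a single test compound are flagged so downstream
    metrics carry the small-sample caveat.
    """
    plan = kfold_cv(table, k=k, seed=seed)
    plan.strategy = "modality_cv"
    rows = []
    for r in plan.rounds:
        cells = pd.DataFrame(sorted(r.test), columns=["smiles_std", "endpoint"])
        cells["modality"] = cells.smiles_std.map(table.modality).fillna("unknown")
        for (ep, mod), grp in cells.groupby(["endpoint", "modality"]):
            rows.append(
                {
                    "round": r.round_id, "endpoint": ep, "modality": mod,
                    "n_test": len(grp), "small_sample": len(grp) <= 1,
                }
            )
    return plan, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# temporal strategies


def default_train_fractions(n_rounds: int = 5, final_frac: float = 0.8) -> list[float]:
    """Evenly spaced cumulative training fractions ending at ``final_frac``."""
    return [final_frac * (r + 1) / n_rounds for r in range(n_rounds)]


def temporal_rounds(
    table: MultitaskTable,
    n_rounds: int = 5,
    mode: str = "leaky",
    train_fractions: list[float] | None = None,
) -> SplitPlan:
    """Time-ordered validation rounds over individual records.

    All (compound, endpoint) records are sorted globally by acquisition date
    (ties broken by SMILES then endpoint for a total order).  Round r trains
    on the oldest cumulative fraction and tests on the remainder, so training
    sets are nested across rounds.  In ``all_for_one`` mode any training
    record whose compound occurs in that round's test set (for any endpoint)
    is dropped from training.
    """
    if mode not in ("leaky", "all_for_one"):
        raise ValueError(f"unknown temporal mode {mode!r}")
    records = table.to_records()
    missing = [
        (r.smiles_std, r.endpoint) for r in records if r.earliest_timestamp is None
    ]
    if missing:
        raise ValueError(f"records without timestamps: {missing[:10]}" +
                         (" ..." if len(missing) > 10 else ""))
    ordered = sorted(records, key=lambda r: (r.earliest_timestamp, r.smiles_std, r.endpoint))
    cells = [(r.smiles_std, r.endpoint) for r in ordered]
    fracs = train_fractions or default_train_fractions(n_rounds)
    if len(fracs) != n_rounds:
        raise ValueError("train_fractions length must equal n_rounds")

    rounds = []
    for i, f in enumerate(fracs):
        n_train = int(round(f * len(cells)))
        train, test = set(cells[:n_train]), set(cells[n_train:])
        if mode == "all_for_one":
            test_smiles = {s for s, _ in test}
            train = {c for c in train if c[0] not in test_smiles}
        rounds.append(Round(i + 1, frozenset(train), frozenset(test)))
    return SplitPlan(
        f"temporal_{mode}", rounds,
        params={"n_rounds": n_rounds, "train_fractions": list(fracs), "mode": mode},
    )


# ---------------------------------------------------------------------------
# leakage


def leakage_report(plan: SplitPlan, table: MultitaskTable) -> LeakageReport:
    """Exact set-arithmetic leakage summary, one row per (endpoint, round)."""
    total = {ep: int(table.mask[ep].sum()) for ep in ENDPOINTS}
    rows = []
    for r in plan.rounds:
        train_smiles = {s for s, _ in r.train}
        for ep in ENDPOINTS:
            test_smiles = {s for s, e in r.test if e == ep}
            if total[ep] == 0:
                continue
            overlap = test_smiles & train_smiles
            rows.append(
                {
                    "endpoint": ep,
                    "round": r.round_id,
                    "test_pct": 100.0 * len(test_smiles) / total[ep],
                    "train_overlap_pct": (
                        100.0 * len(overlap) / len(test_smiles) if test_smiles else 0.0
                    ),
                }
            )
    return LeakageReport(pd.DataFrame(rows))
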