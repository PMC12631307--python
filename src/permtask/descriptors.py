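"""Molecular descriptor blocks for baseline models and network augmentation.

Three tiers mirror the augmentation levels of the multitask models:

* ``plus`` — physicochemical proxies only: a lipophilicity-at-pH-7.4 estimate
  (logD proxy) and the strongest acidic/basic pKa proxies.  Lipophilicity and
  ionization state are the classic modulators of passive permeability and
  efflux recognition.
* ``plusplus`` — the proxies plus eight interpretable 2D descriptors
  (PEOE_VSA1, MolWt, SlogP_VSA1, qed, TPSA, BertzCT, NHOHCount, RingCount).
* ``baseline_full`` — every available 2D descriptor, for tree-ensemble
  baselines; degenerate (constant / all-NaN) columns are dropped at fit time.

The pKa proxies are a deliberately simple SMARTS lookup of typical values for
common ionizable groups (strongest acid = lowest, strongest base = highest);
they capture the ordering of ionization classes, not quantitative pKa.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

logger = logging.getLogger(__name__)

EXTENDED_NAMES = [
    "PEOE_VSA1", "MolWt", "SlogP_VSA1", "qed", "TPSA", "BertzCT",
    "NHOHCount", "RingCount",
]
PROXY_NAMES = ["logd_proxy", "pka_acid_proxy", "pka_base_proxy"]

# typical pKa values of common ionizable groups (strongest acid = min,
# strongest base = max over matches)
_ACID_PATTERNS = [
    ("[CX3](=O)[OX2H1]", 4.0),        # carboxylic acid
    ("c1nnn[nH]1", 4.9),              # tetrazole
    ("[CX3](=O)[NX3H][SX4](=O)(=O)", 4.5),  # acylsulfonamide
    ("[SX4](=O)(=O)[NX3H2]", 10.1),   # primary sulfonamide
    ("c[OX2H]", 10.0),                # phenol
]
_BASE_PATTERNS = [
    ("[NX3H1]C(=[NX2])[NX3]", 12.5),  # guanidine
    ("[NX3;A;!$(NC=O);!$(NS(=O)(=O));!$(N=*);!$(Nc)]", 9.8),  # aliphatic amine
    ("c1cnc[nH]1", 7.0),              # imidazole
    ("[nX2r6]", 5.2),                 # pyridine-like aromatic N
]


def _compile(patterns):
    return [(Chem.MolFromSmarts(s), pka) for s, pka in patterns]


_ACIDS = _compile(_ACID_PATTERNS)
_BASES = _compile(_BASE_PATTERNS)


def pka_proxies(mol: Chem.Mol) -> tuple[float, float]:
    """(strongest acid, strongest base) typical pKa; NaN when no group matches."""
    acids = [pka for patt, pka in _ACIDS if mol.HasSubstructMatch(patt)]
    bases = [pka for patt, pka in _BASES if mol.HasSubstructMatch(patt)]
    return (min(acids) if acids else np.nan, max(bases) if bases else np.nan)


def logd_proxy(mol: Chem.Mol, ph: float = 7.4) -> float:
    """Crippen logP with a Henderson-Hasselbalch ionization correction.

    logD = logP - log10(1 + 10^(pKa_base - pH)) - log10(1 + 10^(pH - pKa_acid));
    missing proxies contribute no correction.
    """
    logp = Crippen.MolLogP(mol)
    pka_acid, pka_base = pka_proxies(mol)
    if np.isfinite(pka_base):
        logp -= np.log10(1 + 10 ** (pka_base - ph))
    if np.isfinite(pka_acid):
        logp -= np.log10(1 + 10 ** (ph - pka_acid))
    return float(logp)


_FULL_DESCRIPTORS = [(name, fn) for name, fn in Descriptors.descList]
_EXTENDED_FNS = {name: dict(Descriptors.descList)[name] for name in EXTENDED_NAMES}


@lru_cache(maxsize=200_000)
def _descriptor_row(smiles: str, which: str) -> tuple:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    pka_acid, pka_base = pka_proxies(mol)
    row = [logd_proxy(mol), pka_acid, pka_base]
    if which == "plus":
        return tuple(row)
    if which == "plusplus":
        for name in EXTENDED_NAMES:
            try:
                row.append(float(_EXTENDED_FNS[name](mol)))
            except Exception:
                row.append(np.nan)
        return tuple(row)
    if which == "baseline_full":
        for _, fn in _FULL_DESCRIPTORS:
            try:
                row.append(float(fn(mol)))
            except Exception:
                row.append(np.nan)
        return tuple(row)
    raise ValueError(f"unknown descriptor set {which!r}")


def descriptor_names(which: str) -> list[str]:
    if which == "plus":
        return list(PROXY_NAMES)
    if which == "plusplus":
        return PROXY_NAMES + EXTENDED_NAMES
    if which == "baseline_full":
        return PROXY_NAMES + [name for name, _ in _FULL_DESCRIPTORS]
    raise ValueError(f"unknown descriptor set {which!r}")


def compute_descriptors(smiles: list[str], which: str = "plusplus") -> pd.DataFrame:
    """Deterministic descriptor block, one row per SMILES.

    Compounds failing descriptor computation get NaN entries (flagged in the
    log) and are median-imputed later, inside model fitting, to keep the
    imputation training-set-only.
    """
    names = descriptor_names(which)
    rows, failed = [], []
    for s in smiles:
        try:
            rows.append(_descriptor_row(s, which))
        except ValueError:
            rows.append(tuple([np.nan] * len(names)))
            failed.append(s)
    if failed:
        logger.warning("descriptor computation failed for %d compounds", len(failed))
    return pd.DataFrame(rows, index=pd.Index(smiles, name="smiles"), columns=names)
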