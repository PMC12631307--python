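"""Synthetic multitask assay-data generator.

Proprietary permeability/efflux training sets cannot ship with a toolkit, so
this module generates raw measurement tables with the *statistical* structure
such data exhibits, making curation, splitting and modeling testable
end-to-end:

* four endpoints driven by one shared, descriptor-derived latent factor plus
  endpoint-specific factors (pairwise correlation = ``latent_correlation``);
* sparse coverage — most compounds measured on a single endpoint
  (57/37/5/1% with 1/2/3/4 endpoints by default);
* heteroscedastic replicate noise, larger at low permeability;
* one endpoint whose assay comes online late in the timeline;
* modality labels dominated by small molecules;
* out-of-quantification-range values reported as censored bounds.

Every draw flows from one seed; regenerating with the same config is
byte-identical.  True log values are kept for every (compound, endpoint),
including unobserved cells, so models can be scored against truth even for
zero-shot endpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy import stats

from . import _fragments as frag
from .curation import ENDPOINTS, RawMeasurement
from .descriptors import compute_descriptors

logger = logging.getLogger(__name__)

_TIMELINE_START = date(2015, 1, 1)
_TIMELINE_DAYS = 3650


def _default_noise_intercept():
    # Papp noise declines with the mean but stays positive over the truth
    # support (zero crossing at m ~ 2.9, beyond ~99% of true values)
    return {"Caco2ER": 0.05, "Caco2Papp": 0.26, "MDCKER": 0.05, "NIHMDCKER": 0.05}


def _default_noise_slope():
    return {"Caco2ER": 0.0, "Caco2Papp": -0.09, "MDCKER": 0.0, "NIHMDCKER": 0.0}


def _default_endpoint_mean():
    return {"Caco2ER": 1.4, "Caco2Papp": 1.3, "MDCKER": 0.6, "NIHMDCKER": 0.65}


def _default_endpoint_scale():
    return {"Caco2ER": 0.6, "Caco2Papp": 0.6, "MDCKER": 0.5, "NIHMDCKER": 0.5}


def _default_censor_limits():
    return {
        "Caco2ER": (-0.5, 3.2),
        "Caco2Papp": (-0.3, 2.9),
        "MDCKER": (-0.7, 2.5),
        "NIHMDCKER": (-0.7, 2.5),
    }


def _default_modality_probs():
    return {"small_molecule": 0.85, "macrocycle": 0.07, "peptide": 0.05, "PROTAC": 0.03}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic assay-data generator.

    Defaults emulate the curated internal dataset the toolkit targets: the
    1/2/3/4-endpoint coverage pattern, strongly correlated endpoints, noisier
    low-permeability wells, a late-start NIH-MDCK-like endpoint at 70% of the
    timeline, and small-molecule-dominated modality labels.
    """

    n_compounds: int = 2000
    coverage_probs: tuple[float, float, float, float] = (0.57, 0.37, 0.05, 0.01)
    latent_correlation: float = 0.8
    endpoint_mean: dict = field(default_factory=_default_endpoint_mean)
    endpoint_scale: dict = field(default_factory=_default_endpoint_scale)
    noise_intercept: dict = field(default_factory=_default_noise_intercept)
    noise_slope: dict = field(default_factory=_default_noise_slope)
    sigma_floor: float = 0.02
    replicate_rate: float = 0.35
    late_endpoint: str = "NIHMDCKER"
    late_start_frac: float = 0.70
    modality_probs: dict = field(default_factory=_default_modality_probs)
    censor_limits: dict = field(default_factory=_default_censor_limits)
    outlier_frac: float = 0.0
    outlier_inflation: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if len(self.coverage_probs) != 4 or abs(sum(self.coverage_probs) - 1) > 1e-9:
            errors.append("coverage_probs must be 4 values summing to 1")
        if not 0 <= self.latent_correlation <= 1:
            errors.append("latent_correlation must be in [0, 1]")
        if self.sigma_floor <= 0:
            errors.append("sigma_floor must be positive")
        if not 0 <= self.replicate_rate <= 1:
            errors.append("replicate_rate must be a probability")
        if self.late_endpoint not in ENDPOINTS:
            errors.append(f"late_endpoint must be one of {ENDPOINTS}")
        if not 0 <= self.late_start_frac < 1:
            errors.append("late_start_frac must be in [0, 1)")
        if abs(sum(self.modality_probs.values()) - 1) > 1e-9:
            errors.append("modality_probs must sum to 1")
        if not 0 <= self.outlier_frac < 1:
            errors.append("outlier_frac must be in [0, 1)")
        if errors:
            raise ValueError("invalid generator config: " + "; ".join(errors))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        data = dict(data)
        if "coverage_probs" in data:
            data["coverage_probs"] = tuple(data["coverage_probs"])
        if "censor_limits" in data:
            data["censor_limits"] = {
                k: tuple(v) if v is not None else None
                for k, v in data["censor_limits"].items()
            }
        return cls(**data)


@dataclass
class SyntheticDataset:
    """Generated measurements plus the ground truth that produced them."""

    measurements: list[RawMeasurement]
    truth: pd.DataFrame  # index smiles, columns ENDPOINTS (true log values)
    modality: pd.Series
    config: GeneratorConfig
    outlier_cells: set[tuple[str, str]] = field(default_factory=set)

    @property
    def smiles(self) -> list[str]:
        return list(self.truth.index)


# ---------------------------------------------------------------------------
# molecule library


def _sample_small_molecule(rng) -> str:
    if rng.random() < 0.55:
        core = frag.CORES_1[rng.integers(len(frag.CORES_1))]
        return core.format(r1=frag.SUBSTITUENTS[rng.integers(len(frag.SUBSTITUENTS))])
    core = frag.CORES_2[rng.integers(len(frag.CORES_2))]
    return core.format(
        r1=frag.SUBSTITUENTS[rng.integers(len(frag.SUBSTITUENTS))],
        r2=frag.SUBSTITUENTS[rng.integers(len(frag.SUBSTITUENTS))],
    )


def _sample_macrocycle(rng) -> str:
    n_units = int(rng.integers(4, 8))
    units = [frag.MACROCYCLE_UNITS[rng.integers(len(frag.MACROCYCLE_UNITS))] for _ in range(n_units)]
    side = None
    if rng.random() < 0.5:
        side = frag.SUBSTITUENTS[rng.integers(len(frag.SUBSTITUENTS))]
    return frag.macrocycle_smiles(units, side)


def _sample_peptide(rng) -> str:
    n_res = int(rng.integers(2, 5))
    sides = [
        frag.PEPTIDE_SIDE_CHAINS[rng.integers(len(frag.PEPTIDE_SIDE_CHAINS))]
        for _ in range(n_res)
    ]
    return frag.peptide_smiles(sides)


def _sample_protac(rng) -> str:
    template = frag.PROTAC_TEMPLATE if rng.random() < 0.5 else frag.PROTAC_TEMPLATE_ME
    return template.format(
        head=frag.PROTAC_HEADS[rng.integers(len(frag.PROTAC_HEADS))],
        linker=frag.PROTAC_LINKERS[rng.integers(len(frag.PROTAC_LINKERS))],
        tail=frag.PROTAC_TAILS[rng.integers(len(frag.PROTAC_TAILS))],
    )


_SAMPLERS = {
    "small_molecule": _sample_small_molecule,
    "macrocycle": _sample_macrocycle,
    "peptide": _sample_peptide,
    "PROTAC": _sample_protac,
}


def sample_library(
    n: int,
    seed: int = 0,
    modality_probs: dict | None = None,
    return_modality: bool = False,
):
    """Draw ``n`` distinct, parseable canonical SMILES from the grammar.

    Candidates are assembled from the packaged fragment grammar, canonicalized
    with RDKit and de-duplicated.  Raises if the grammar cannot supply ``n``
    distinct molecules.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    probs = modality_probs or _default_modality_probs()
    rng = np.random.default_rng(seed)
    names = sorted(probs)
    p = np.array([probs[k] for k in names])
    seen: set[str] = set()
    smiles: list[str] = []
    modalities: list[str] = []
    attempts = 0
    max_attempts = 200 * n
    while len(smiles) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"fragment grammar exhausted: produced {len(smiles)} of {n} "
                "distinct molecules"
            )
        modality = names[rng.choice(len(names), p=p)]
        candidate = _SAMPLERS[modality](rng)
        mol = Chem.MolFromSmiles(candidate)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        smiles.append(canonical)
        modalities.append(modality)
    if return_modality:
        return smiles, modalities
    return smiles


# ---------------------------------------------------------------------------
# latent truth


def latent_truth(
    descriptors: pd.DataFrame, config: GeneratorConfig, seed: int = 0
) -> pd.DataFrame:
    """True log values: shared descriptor-derived factor + specific factors.

    The shared factor loads on the physchem proxies (lipophilicity, polar
    surface area, size) so descriptor augmentation has real signal to find.
    Each endpoint value is mean + scale * (sqrt(rho)*g + sqrt(1-rho)*eps);
    the P_app-like endpoint's specific factor is a standardized lognormal,
    giving the right-skewed distribution permeability data show, while the
    ER-like endpoints stay unimodal.
    """
    rng = np.random.default_rng(seed)

    def z(col):
        v = descriptors[col].to_numpy(float)
        v = np.where(np.isfinite(v), v, np.nanmean(v[np.isfinite(v)]))
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    score = 0.8 * z("logd_proxy") - 0.5 * z("TPSA") - 0.3 * z("MolWt")
    # rank-based inverse-normal transform: the shared factor keeps the
    # descriptor ordering but is exactly standard-normal shaped, so endpoint
    # skewness is controlled by the specific factors below
    g = stats.norm.ppf((stats.rankdata(score) - 0.5) / len(score))

    rho = config.latent_correlation
    n = len(descriptors)
    out = {}
    for ep in ENDPOINTS:
        if ep == "Caco2Papp":
            # standardized lognormal: right-skewed but with a moderate tail,
            # keeping true permeabilities physically plausible
            s = 0.6
            zz = rng.standard_normal(n)
            eps = (np.exp(s * zz) - np.exp(s**2 / 2)) / np.sqrt(
                (np.exp(s**2) - 1) * np.exp(s**2)
            )
        else:
            eps = rng.standard_normal(n)
        latent = np.sqrt(rho) * g + np.sqrt(1 - rho) * eps
        out[ep] = config.endpoint_mean[ep] + config.endpoint_scale[ep] * latent
    return pd.DataFrame(out, index=descriptors.index)[list(ENDPOINTS)]


# ---------------------------------------------------------------------------
# measurement machinery


def _replicates(true_value, endpoint, config, rng, outlier=False):
    sigma = max(
        config.sigma_floor,
        config.noise_intercept[endpoint] + config.noise_slope[endpoint] * true_value,
    )
    if outlier:
        # inconsistent compounds get remeasured: more replicates, inflated spread
        sigma *= config.outlier_inflation
        count = int(rng.integers(4, 7))
    else:
        count = 1 if rng.random() >= config.replicate_rate else int(rng.integers(2, 5))
    return list(true_value + sigma * rng.standard_normal(count))


def make_replicates(
    true_value: float, endpoint: str, config: GeneratorConfig, seed: int = 0
) -> list[float]:
    """Gaussian replicate log values around the truth with sigma(mean)."""
    return _replicates(true_value, endpoint, config, np.random.default_rng(seed))


def censor(
    values: list[float], limits: tuple[float, float] | None
) -> list[tuple[float, str]]:
    """Clip out-of-quantification-range values and record the bound direction."""
    if limits is None:
        return [(v, "none") for v in values]
    lo, hi = limits
    out = []
    for v in values:
        if v < lo:
            out.append((lo, "lower_bound"))
        elif v > hi:
            out.append((hi, "upper_bound"))
        else:
            out.append((v, "none"))
    return out


def assign_coverage_and_time(
    smiles: list[str], config: GeneratorConfig, seed: int = 0
) -> dict[str, list[tuple[str, float]]]:
    """Pick measured endpoints and timeline positions per compound.

    Endpoint counts follow ``coverage_probs``; timestamps are uniform over the
    timeline except for the late endpoint, whose measurements all postdate its
    start fraction.
    """
    rng = np.random.default_rng(seed)
    counts = rng.choice([1, 2, 3, 4], size=len(smiles), p=list(config.coverage_probs))
    out: dict[str, list[tuple[str, float]]] = {}
    for smi, k in zip(smiles, counts):
        eps = [ENDPOINTS[i] for i in rng.choice(4, size=int(k), replace=False)]
        cells = []
        for ep in sorted(eps):
            lo = config.late_start_frac if ep == config.late_endpoint else 0.0
            cells.append((ep, float(rng.uniform(lo, 1.0))))
        out[smi] = cells
    return out


def _frac_to_date(frac: float) -> date:
    return _TIMELINE_START + timedelta(days=int(frac * _TIMELINE_DAYS))


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Generate a full raw measurement table plus ground truth."""
    root = np.random.SeedSequence(config.seed)
    s_lib, s_truth, s_cov, s_noise, s_out = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(5)
    ]

    smiles, modalities = sample_library(
        config.n_compounds, seed=s_lib, modality_probs=config.modality_probs,
        return_modality=True,
    )
    modality = pd.Series(modalities, index=smiles, dtype=object)
    descriptors = compute_descriptors(smiles, which="plusplus")
    truth = latent_truth(descriptors, config, seed=s_truth)
    coverage = assign_coverage_and_time(smiles, config, seed=s_cov)

    # choose planted-outlier cells among observed cells
    all_cells = [(smi, ep) for smi in smiles for ep, _ in coverage[smi]]
    outlier_cells: set[tuple[str, str]] = set()
    if config.outlier_frac > 0:
        rng_out = np.random.default_rng(s_out)
        n_out = int(round(config.outlier_frac * len(all_cells)))
        idx = rng_out.choice(len(all_cells), size=n_out, replace=False)
        outlier_cells = {all_cells[i] for i in sorted(idx)}

    rng = np.random.default_rng(s_noise)
    measurements: list[RawMeasurement] = []
    for smi in smiles:
        for ep, frac in coverage[smi]:
            true_value = float(truth.at[smi, ep])
            logs = _replicates(
                true_value, ep, config, rng, outlier=(smi, ep) in outlier_cells
            )
            for value, qualifier in censor(logs, config.censor_limits.get(ep)):
                measurements.append(
                    RawMeasurement(
                        smiles=smi,
                        endpoint=ep,
                        value=10.0 ** value,
                        qualifier=qualifier,
                        timestamp=_frac_to_date(frac),
                        modality=str(modality.at[smi]),
                    )
                )
    return SyntheticDataset(
        measurements=measurements, truth=truth, modality=modality, config=config,
        outlier_cells=outlier_cells,
    )
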