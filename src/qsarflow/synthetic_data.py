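"""Synthetic descriptor-activity datasets and published-table fixtures.

The generator emulates the statistical regime of a small AChE-inhibitor
QSAR study: ~50 compounds, ~50 molecular descriptors of which exactly
three (polar surface area PSA, dipole moment DM, molecular weight MW)
drive the activity through a known linear model, the rest being nuisance
columns, exact duplicates and constants.  Activities are

    pIC50 = b0 + sum_j b_j x_j + eps,    eps ~ Normal(0, noise_sd^2),

with correlated multivariate-normal informative descriptors.  The default
specification is calibrated so a three-descriptor OLS fit on a 50-compound
draw lands near the reported training R^2 of about 0.64 and yields
activities mostly inside the published 5.3-7.3 pIC50 range.

Fixtures transcribe the published candidate-design, drug-likeness, ADMET
and activity tables so every downstream stage is testable offline.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .dataset_io import CompoundRecord, Dataset
from .errors import ConfigurationError, FixtureLookupError
from .mlr_core import MLRModel
from .screening import ADMETProfile

__all__ = [
    "SyntheticSpec",
    "generate_dataset",
    "default_paperlike_spec",
    "load_fixture",
    "fixture_frame",
    "admet_profiles",
    "FIXTURE_NAMES",
]


@dataclass
class SyntheticSpec:
    """Full description of one synthetic dataset draw."""

    n: int
    k_informative: int
    k_noise: int
    beta0: float
    betas: list[float]
    descriptor_means: list[float]
    descriptor_sds: list[float]
    inter_correlation: np.ndarray
    noise_sd: float
    n_constant_cols: int = 0
    n_duplicate_cols: int = 0
    seed: int = 0
    informative_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        k = self.k_informative
        if len(self.betas) != k:
            raise ConfigurationError(f"need {k} betas, got {len(self.betas)}")
        if len(self.descriptor_means) != k or len(self.descriptor_sds) != k:
            raise ConfigurationError("descriptor_means/sds must match k_informative")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        corr = np.asarray(self.inter_correlation, dtype=float)
        if corr.shape != (k, k) or not np.allclose(corr, corr.T):
            raise ConfigurationError("inter_correlation must be a symmetric k x k matrix")
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            raise ConfigurationError(
                "inter_correlation is not positive-definite"
            ) from None
        self.inter_correlation = corr
        if not self.informative_names:
            self.informative_names = [f"d{j + 1}" for j in range(k)]
        if self.n_duplicate_cols > self.k_informative + self.k_noise:
            raise ConfigurationError("more duplicate columns than source columns")


def default_paperlike_spec(seed: int = 0) -> SyntheticSpec:
    """Study-like default: 50 compounds, 50 columns, 3 true drivers.

    Slopes are the published model coefficients (PSA -0.007 per A^2,
    DM +0.163 per Debye, MW +0.010 per g/mol).  Descriptor locations,
    spreads and inter-correlations are chosen so that (a) the
    standardized-effect ordering is MW > DM > PSA, (b) activities fall
    predominantly in [5.0, 7.6], (c) each driver keeps a marginal
    activity correlation strong enough to be found among ~47 nuisance
    columns, and (d) with noise_sd = 0.53 the median training R^2 over
    many 50-compound draws sits in the 0.55-0.72 band around the
    reported 0.64 (see scripts/calibrate_noise.py).
    """
    corr = np.array(
        [
            [1.0, -0.5, -0.5],
            [-0.5, 1.0, 0.5],
            [-0.5, 0.5, 1.0],
        ]
    )
    return SyntheticSpec(
        n=50,
        k_informative=3,
        k_noise=43,
        beta0=2.587,
        betas=[-0.007, 0.163, 0.010],
        descriptor_means=[60.0, 3.5, 360.0],
        descriptor_sds=[30.0, 1.5, 40.0],
        inter_correlation=corr,
        noise_sd=0.53,
        n_constant_cols=2,
        n_duplicate_cols=2,
        seed=seed,
        informative_names=["PSA", "DM", "MW"],
    )


def generate_dataset(spec: SyntheticSpec) -> Dataset:
    """Draw one dataset; fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    k = spec.k_informative
    sds = np.asarray(spec.descriptor_sds, dtype=float)
    cov = spec.inter_correlation * np.outer(sds, sds)
    X_inf = rng.multivariate_normal(
        np.asarray(spec.descriptor_means, dtype=float), cov, size=spec.n,
        method="cholesky",
    )
    y = (
        spec.beta0
        + X_inf @ np.asarray(spec.betas, dtype=float)
        + spec.noise_sd * rng.standard_normal(spec.n)
    )

    names = list(spec.informative_names)
    columns = [X_inf[:, j] for j in range(k)]
    # nuisance columns at loosely descriptor-like scales
    for j in range(spec.k_noise):
        loc = rng.uniform(0.0, 100.0)
        scale = rng.uniform(0.5, 20.0)
        columns.append(loc + scale * rng.standard_normal(spec.n))
        names.append(f"noise{j + 1:02d}")
    for j in range(spec.n_constant_cols):
        columns.append(np.full(spec.n, round(rng.uniform(0.0, 10.0), 3)))
        names.append(f"const{j + 1:02d}")
    for j in range(spec.n_duplicate_cols):
        src = k + j if spec.k_noise > j else j  # prefer duplicating noise columns
        columns.append(columns[src].copy())
        names.append(f"dup_of_{names[src]}")

    width = len(str(spec.n))
    records = [
        CompoundRecord(
            id=f"S{i + 1:0{width}d}",
            descriptors={name: float(col[i]) for name, col in zip(names, columns)},
            pic50=float(y[i]),
        )
        for i in range(spec.n)
    ]
    return Dataset(records, names)


# ---------------------------------------------------------------------------
# published-table fixtures

FIXTURE_NAMES = (
    "eq1_model",
    "table4_candidates",
    "table5_druglikeness",
    "table6_admet",
    "table8_activities",
)

_CSV_FIXTURES = {
    "table4_candidates": "table4_candidates.csv",
    "table5_druglikeness": "table5_druglikeness.csv",
    "table6_admet": "table6_admet.csv",
    "table8_activities": "table8_activities.csv",
}


def fixture_frame(name: str) -> pd.DataFrame:
    """Raw DataFrame of a CSV fixture, printed columns included."""
    if name not in _CSV_FIXTURES:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; valid names: {sorted(_CSV_FIXTURES)}"
        )
    path = importlib.resources.files("qsarflow.data") / _CSV_FIXTURES[name]
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p)


def _eq1_model() -> MLRModel:
    """Published three-descriptor model, statistics from its closed forms.

    The printed training statistics (R^2 = 0.64, RMSE = 0.35, n = 40) are
    attached as-is; F and its p-value are recomputed from the R^2/F
    identity so the model object stays internally consistent (the printed
    F of 21.54 reflects an unrounded R^2).
    """
    r2, k, n = 0.64, 3, 40
    f_stat = (r2 / k) / ((1 - r2) / (n - k - 1))
    f_pvalue = float(scipy.stats.f.sf(f_stat, k, n - k - 1))
    rmse = 0.35
    return MLRModel(
        intercept=2.587,
        coefficients={"PSA": -0.007, "DM": 0.163, "MW": 0.010},
        n_train=n,
        r2=r2,
        rmse=rmse,
        residual_sd=rmse * float(np.sqrt(n / (n - k - 1))),
        f_stat=f_stat,
        f_pvalue=f_pvalue,
    )


def _table4_dataset() -> Dataset:
    frame = fixture_frame("table4_candidates")
    records = [
        CompoundRecord(
            id=row["id"],
            descriptors={"PSA": row["PSA"], "DM": row["DM"], "MW": row["MW"]},
        )
        for _, row in frame.iterrows()
    ]
    return Dataset(records, ["PSA", "DM", "MW"])


def _bool(cell: str) -> bool:
    return str(cell).strip().lower() in ("yes", "true", "1")


def load_fixture(name: str):
    """Load a published-table fixture by name.

    Returns an :class:`MLRModel` for ``eq1_model``, a :class:`Dataset`
    of the 11 designed candidates for ``table4_candidates``, DataFrames
    for the drug-likeness and ADMET tables, and the ordered array of the
    50 training-series pIC50 values for ``table8_activities``.
    """
    if name not in FIXTURE_NAMES:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; valid names: {sorted(FIXTURE_NAMES)}"
        )
    if name == "eq1_model":
        return _eq1_model()
    if name == "table4_candidates":
        return _table4_dataset()
    if name == "table8_activities":
        return fixture_frame(name)["pIC50"].to_numpy(dtype=float)
    frame = fixture_frame(name)
    if name == "table6_admet":
        for col in ("cyp2d6_inhibitor", "ames_toxic", "hepatotoxic", "skin_sensitizer"):
            frame[col] = frame[col].map(_bool)
    return frame.set_index("id")


def admet_profiles() -> dict[str, ADMETProfile]:
    """Merged drug-likeness + ADMET profiles for the candidates in both tables."""
    t5 = load_fixture("table5_druglikeness")
    t6 = load_fixture("table6_admet")
    out = {}
    for cid in t5.index:
        row5, row6 = t5.loc[cid], t6.loc[cid]
        out[cid] = ADMETProfile(
            id=cid,
            logp=float(row5["logp"]),
            mw=float(row5["mw"]),
            hba=int(row5["hba"]),
            hbd=int(row5["hbd"]),
            caco2=float(row6["caco2"]),
            hia=float(row6["hia"]),
            logbb=float(row6["logbb"]),
            logps=float(row6["logps"]),
            cyp2d6_inhibitor=bool(row6["cyp2d6_inhibitor"]),
            total_clearance=float(row6["total_clearance"]),
            ames_toxic=bool(row6["ames_toxic"]),
            ld50=float(row6["ld50"]),
            hepatotoxic=bool(row6["hepatotoxic"]),
            skin_sensitizer=bool(row6["skin_sensitizer"]),
        )
    return out
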