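"""Synthetic study generation for the similarity-weighted prior simulation.

Generates a focal regression study and a database of K previously
conducted studies whose true coefficient vectors scatter around
meta-analytic means with between-study variance ``tau2``, plus one
study-level moderator that accounts for an additional ``moderator_r2``
fraction of that variance.  Also enumerates the full simulation design
grid with reproducible per-condition seeds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimCondition",
    "TrueParams",
    "RegressionDataset",
    "StudyDatabase",
    "PAPER_GRID",
    "DEFAULT_TRUE_PARAMS",
    "total_heterogeneity",
    "enumerate_grid",
    "generate_focal",
    "generate_database",
    "write_database",
    "read_database",
    "write_conditions",
]

# Design-grid factor levels of the simulation study: number of previous
# studies, sample-size offset, predictor mean offset, between-study variance.
PAPER_GRID = {
    "K": (3, 5, 10),
    "delta_N": (-100, 100),
    "delta_mu": (0.25, 0.5, 1.0, 2.0, 3.0),
    "tau2": (0.025, 0.05, 0.10, 0.15, 0.20, 0.35, 0.5),
}

_SEED_MOD = 2**31


class InvalidDesignError(ValueError):
    """Raised when a simulation design grid is empty or malformed."""


@dataclass(frozen=True)
class SimCondition:
    """One cell of the simulation design grid."""

    K: int
    delta_N: int
    delta_mu: float
    tau2: float
    moderator_r2: float = 0.1
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError(f"K must be >= 2, got {self.K}")
        if self.tau2 <= 0:
            raise ValueError(f"tau2 must be > 0, got {self.tau2}")
        if not 0 <= self.moderator_r2 < 1:
            raise ValueError(f"moderator_r2 must be in [0, 1), got {self.moderator_r2}")
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")


@dataclass(frozen=True)
class TrueParams:
    """Generating parameters shared across the design grid.

    ``beta_F`` are the focal study's true coefficients and ``mu_beta_k``
    the meta-analytic means around which previous-study coefficients are
    drawn; the defaults encode certainty (0.5 vs 0.4), disagreement
    (0.25 vs 0.0) and contradiction (-0.5 vs 0.3) in effect size.
    """

    beta_F: tuple = (0.5, 0.25, -0.5)
    mu_beta_k: tuple = (0.4, 0.0, 0.3)
    sigma2: float = 1.0
    N_F: int = 200

    def __post_init__(self) -> None:
        if len(self.beta_F) != len(self.mu_beta_k):
            raise ValueError("beta_F and mu_beta_k must have equal length")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if self.N_F < len(self.beta_F) + 4:
            raise ValueError("N_F must be at least p + 4")

    @property
    def p(self) -> int:
        return len(self.beta_F)


DEFAULT_TRUE_PARAMS = TrueParams()


@dataclass
class RegressionDataset:
    """One study's outcome vector and predictor matrix."""

    y: np.ndarray
    X: np.ndarray
    study_id: str = ""

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.y.ndim != 1 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X rows must match length of y")
        if self.X.shape[1] < 1:
            raise ValueError("need at least one predictor column")
        if not (np.isfinite(self.y).all() and np.isfinite(self.X).all()):
            raise ValueError("dataset contains non-finite values")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class StudyDatabase:
    """Ordered collection of previously conducted studies.

    ``true_betas`` retains the generating coefficient vectors for
    evaluation only; the analysis pipeline never reads them.
    """

    studies: list
    moderators: np.ndarray
    true_betas: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if len(self.studies) < 1:
            raise ValueError("database needs at least one study")
        self.moderators = np.asarray(self.moderators, dtype=float)
        if self.moderators.shape[0] != len(self.studies):
            raise ValueError("moderators must align with studies")

    @property
    def K(self) -> int:
        return len(self.studies)

    @property
    def p(self) -> int:
        return self.studies[0].p


def total_heterogeneity(tau2: float, moderator_r2: float = 0.1) -> float:
    """Design-level total heterogeneity tau2 + delta_tau2.

    The moderator explains an additional ``moderator_r2`` fraction of
    the between-study variance on top of ``tau2``, so the simulated
    total is ``(1 + moderator_r2) * tau2`` (e.g. 0.0275 for tau2=0.025).
    """
    return tau2 * (1.0 + moderator_r2)


def _child_seed(base_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), *[int(k) & 0x7FFFFFFF for k in key]])
    return int(ss.generate_state(1)[0]) % _SEED_MOD


def enumerate_grid(
    levels_K: Sequence[int] = PAPER_GRID["K"],
    levels_dN: Sequence[int] = PAPER_GRID["delta_N"],
    levels_dMu: Sequence[float] = PAPER_GRID["delta_mu"],
    levels_tau2: Sequence[float] = PAPER_GRID["tau2"],
    n_reps: int = 100,
    base_seed: int = 0,
    moderator_r2: float = 0.1,
) -> list:
    """Cartesian product of the design factors as SimCondition objects.

    Each condition receives a deterministic, distinct seed derived from
    ``base_seed`` and its grid index, so conditions can be regenerated
    independently and in any order.
    """
    for name, lv in (
        ("levels_K", levels_K),
        ("levels_dN", levels_dN),
        ("levels_dMu", levels_dMu),
        ("levels_tau2", levels_tau2),
    ):
        if len(lv) == 0:
            raise InvalidDesignError(f"{name} is empty")
    conditions = []
    for i, (K, dN, dMu, t2) in enumerate(
        itertools.product(levels_K, levels_dN, levels_dMu, levels_tau2)
    ):
        conditions.append(
            SimCondition(
                K=K,
                delta_N=dN,
                delta_mu=dMu,
                tau2=t2,
                moderator_r2=moderator_r2,
                n_reps=n_reps,
                seed=_child_seed(base_seed, i),
            )
        )
    return conditions


def generate_focal(true_params: TrueParams, seed: int) -> RegressionDataset:
    """Simulate the focal study: X ~ N(0,1) columns, y = X beta_F + eps."""
    rng = np.random.default_rng(seed)
    p = true_params.p
    X = rng.standard_normal((true_params.N_F, p))
    eps = rng.normal(0.0, np.sqrt(true_params.sigma2), size=true_params.N_F)
    y = X @ np.asarray(true_params.beta_F, dtype=float) + eps
    return RegressionDataset(y=y, X=X, study_id="focal")


def generate_database(
    cond: SimCondition, true_params: TrueParams, seed: int
) -> StudyDatabase:
    """Simulate the database of K previously conducted studies.

    Per study k: sample size n_k ~ round(N(N_F + delta_N, var 25)), floored
    at p+4; moderator m_k ~ N(0,1); coefficients
    beta_k = mu_beta + sqrt(moderator_r2 * tau2) * m_k + e_k with
    e_k ~ N(0, tau2 * I), so the total coefficient variance is
    (1 + moderator_r2) * tau2 of which the moderator explains
    moderator_r2 * tau2; predictors ~ N(delta_mu, 1); errors ~ N(0, 1).
    """
    rng = np.random.default_rng(seed)
    p = true_params.p
    mu_beta = np.asarray(true_params.mu_beta_k, dtype=float)
    gamma = np.sqrt(cond.moderator_r2 * cond.tau2)
    sd_resid = np.sqrt(cond.tau2)

    studies, moderators, betas = [], [], []
    n_mean = true_params.N_F + cond.delta_N
    for k in range(cond.K):
        n_k = max(int(np.rint(rng.normal(n_mean, 5.0))), p + 4)
        m_k = rng.standard_normal()
        beta_k = mu_beta + gamma * m_k + rng.normal(0.0, sd_resid, size=p)
        X_k = rng.normal(cond.delta_mu, 1.0, size=(n_k, p))
        y_k = X_k @ beta_k + rng.standard_normal(n_k)
        studies.append(RegressionDataset(y=y_k, X=X_k, study_id=f"study_{k + 1}"))
        moderators.append(m_k)
        betas.append(beta_k)
    return StudyDatabase(
        studies=studies,
        moderators=np.array(moderators),
        true_betas=np.array(betas),
    )


# ---------------------------------------------------------------------------
# CSV interchange: long-format study table `study_id, y, x1..xp`, moderator
# table `study_id, m`, and one-row-per-cell condition table.

def _dataset_frame(ds: RegressionDataset) -> pd.DataFrame:
    cols = {"study_id": ds.study_id, "y": ds.y}
    for j in range(ds.p):
        cols[f"x{j + 1}"] = ds.X[:, j]
    return pd.DataFrame(cols)


def write_database(
    db: StudyDatabase, out_dir: str | Path, focal: RegressionDataset | None = None
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = [_dataset_frame(s) for s in db.studies]
    pd.concat(frames, ignore_index=True).to_csv(out / "studies.csv", index=False)
    pd.DataFrame(
        {"study_id": [s.study_id for s in db.studies], "m": db.moderators}
    ).to_csv(out / "moderators.csv", index=False)
    if focal is not None:
        _dataset_frame(focal).to_csv(out / "focal.csv", index=False)


def read_dataset(path: str | Path, study_id: str | None = None) -> RegressionDataset:
    df = pd.read_csv(path)
    if study_id is not None:
        df = df[df["study_id"] == study_id]
    xcols = sorted(
        (c for c in df.columns if c.startswith("x")), key=lambda c: int(c[1:])
    )
    sid = str(df["study_id"].iloc[0]) if "study_id" in df else ""
    return RegressionDataset(
        y=df["y"].to_numpy(), X=df[xcols].to_numpy(), study_id=sid
    )


def read_database(dir_path: str | Path) -> StudyDatabase:
    d = Path(dir_path)
    df = pd.read_csv(d / "studies.csv")
    mods = pd.read_csv(d / "moderators.csv")
    xcols = sorted(
        (c for c in df.columns if c.startswith("x")), key=lambda c: int(c[1:])
    )
    studies = []
    for sid in mods["study_id"].astype(str):
        sub = df[df["study_id"].astype(str) == sid]
        studies.append(
            RegressionDataset(
                y=sub["y"].to_numpy(), X=sub[xcols].to_numpy(), study_id=sid
            )
        )
    return StudyDatabase(studies=studies, moderators=mods["m"].to_numpy())


def write_conditions(conditions: Sequence[SimCondition], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "K": c.K,
                "delta_N": c.delta_N,
                "delta_mu": c.delta_mu,
                "tau2": c.tau2,
                "moderator_r2": c.moderator_r2,
                "n_reps": c.n_reps,
                "seed": c.seed,
            }
            for c in conditions
        ]
    ).to_csv(path, index=False)


def replication_seed(cond: SimCondition, rep: int, stream: int = 0) -> int:
    """Deterministic child seed for replication ``rep`` of a condition.

    ``stream`` separates independent consumers (0 = focal data,
    1 = database, 2+ = model fits) so adding a consumer never shifts
    the draws of another.
    """
    return _child_seed(cond.seed, rep, stream)
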