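"""Ant-colony-optimization wrapper feature selection over color components.

Each of the 36 color components is a node with two states, include or
exclude; an ant's path is a boolean mask over components.  Pheromone
tau(component, state) starts at tau0 = 1 and drives the state choice via

    p(state) = tau^alpha * eta^beta / sum_states tau^alpha * eta^beta

(alpha = beta = 1 by default).  Visibility eta defaults to the absolute
Pearson correlation between a component and the OD target on the
calibration set (include state eta = |r|, exclude state eta = 1 - |r|):
it aims the initial search at plausibly informative components, which the
pheromone alone cannot do from a uniform start.  A uniform mode — eta
carrying no information, selection driven purely by pheromone — is also
available and is what :func:`run_on_costs` uses by default.  Every ant's
subset is scored by training a BPNN on the calibration samples restricted
to the subset and computing the weighted mean absolute deviation

    BestCost = 0.75 * mean|e_cal| + 0.25 * mean|e_val|

— smaller is better.  Each ant deposits Q / cost on the states it chose
(the ant-cycle rule: shorter "path", bigger deposit), and pheromone
evaporates each iteration.  The default evaporation is the conventional
(1 - rho) * tau + deposits with rho = 0.05; a ``literal`` mode instead
multiplies old pheromone by rho itself (95% loss per iteration), kept as
an option because the printed update rule reads that way.

A full experiment repeats the optimization from independent seeds
(50 in the study protocol) and tallies how often each component appears
in the per-run best subset; thresholding that frequency table yields the
final sensor component sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .bpnn import BPNNRegressor, TrainConfig, TrainingDivergedError
from .evaluation import SplitDataset, r2, rmse

__all__ = [
    "ACOConfig",
    "PheromoneTable",
    "AntSolution",
    "RunResult",
    "FrequencyTable",
    "selection_probabilities",
    "construct_subset",
    "best_cost",
    "evaluate_subset",
    "deposit_amount",
    "update_pheromone",
    "run",
    "run_on_costs",
    "repeat_runs",
    "select_by_frequency",
    "ACOFeatureSelector",
]

_EPS_COST = 1e-12     # guard for a perfect (zero-cost) solution
_TAU_FLOOR = 1e-6     # pheromone never decays below this
_IMPROVE_TOL = 1e-6   # minimum cost decrease counted as an improvement

EXCLUDE, INCLUDE = 0, 1


@dataclass(frozen=True)
class ACOConfig:
    """ACO hyperparameters (defaults are the study protocol's)."""

    n_ants: int = 20
    max_iterations: int = 100
    initial_pheromone: float = 1.0
    pheromone_weight: float = 1.0   # alpha
    visibility_weight: float = 1.0  # beta
    evaporation: float = 0.05       # rho
    deposit_total: float = 1.0      # Q
    evaporation_mode: str = "conventional"  # or "literal"
    visibility_mode: str = "abs_correlation"  # or "uniform"
    min_subset_size: int = 1
    train_weight: float = 0.75
    test_weight: float = 0.25
    seed: int | None = None

    def __post_init__(self) -> None:
        if abs(self.train_weight + self.test_weight - 1.0) > 1e-12:
            raise ValueError("train_weight + test_weight must equal 1")
        if not 0 < self.evaporation < 1:
            raise ValueError("evaporation must lie in (0, 1)")
        if self.n_ants < 1:
            raise ValueError("need at least one ant")
        if self.evaporation_mode not in ("conventional", "literal"):
            raise ValueError("evaporation_mode must be conventional|literal")
        if self.visibility_mode not in ("uniform", "abs_correlation"):
            raise ValueError("visibility_mode must be uniform|abs_correlation")


@dataclass
class PheromoneTable:
    """tau and eta per (component, state); columns are [exclude, include]."""

    tau: np.ndarray
    eta: np.ndarray

    def __post_init__(self) -> None:
        if self.tau.shape != self.eta.shape or self.tau.shape[1] != 2:
            raise ValueError("tau/eta must be (n_components, 2)")
        if np.any(self.tau <= 0) or np.any(self.eta <= 0):
            raise ValueError("tau and eta must be positive")

    @classmethod
    def fresh(cls, n_components: int, config: ACOConfig,
              eta: np.ndarray | None = None) -> "PheromoneTable":
        tau = np.full((n_components, 2), config.initial_pheromone, dtype=float)
        if eta is None:
            eta = np.ones((n_components, 2))
        return cls(tau=tau, eta=np.asarray(eta, dtype=float))


@dataclass
class AntSolution:
    """One ant's constructed subset and its wrapper evaluation."""

    mask: np.ndarray
    cost: float
    metrics: dict = field(default_factory=dict)


@dataclass
class RunResult:
    """Outcome of one optimization run."""

    best_solution: AntSolution
    convergence_curve: np.ndarray   # best-so-far cost per iteration
    convergence_iteration: int      # last iteration improving best cost
    seed: int | None


@dataclass
class FrequencyTable:
    """Per-component inclusion counts over the best subsets of many runs."""

    counts: np.ndarray
    n_runs: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if np.any(c < 0) or np.any(c > self.n_runs):
            raise ValueError("counts must lie in [0, n_runs]")
        self.counts = c


def selection_probabilities(tau_pair, eta_pair, alpha: float = 1.0,
                            beta: float = 1.0) -> np.ndarray:
    """State probabilities p_j = tau_j^alpha eta_j^beta / sum over states."""
    tau = np.asarray(tau_pair, dtype=float)
    eta = np.asarray(eta_pair, dtype=float)
    if np.any(tau <= 0) or np.any(eta <= 0):
        raise ValueError("tau and eta must be positive")
    w = tau ** alpha * eta ** beta
    return w / w.sum()


def construct_subset(table: PheromoneTable, config: ACOConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Sample each component's include/exclude state independently.

    If fewer than ``min_subset_size`` components land in the subset, the
    components with the highest include-probability are forced in.
    """
    w = table.tau ** config.pheromone_weight * table.eta ** config.visibility_weight
    p_include = w[:, INCLUDE] / w.sum(axis=1)
    mask = rng.random(table.tau.shape[0]) < p_include
    deficit = config.min_subset_size - int(mask.sum())
    if deficit > 0:
        order = np.argsort(-p_include, kind="stable")
        forced = [i for i in order if not mask[i]][:deficit]
        mask[forced] = True
    return mask


def best_cost(deviations_train, deviations_test,
              train_weight: float = 0.75, test_weight: float = 0.25) -> float:
    """Weighted mean absolute deviation over calibration and validation."""
    dt = np.asarray(deviations_train, dtype=float)
    dv = np.asarray(deviations_test, dtype=float)
    if dt.size == 0 or dv.size == 0:
        raise ValueError("deviation vectors must be non-empty")
    return float(train_weight * np.abs(dt).mean()
                 + test_weight * np.abs(dv).mean())


def evaluate_subset(mask: np.ndarray, split: SplitDataset,
                    train_config: TrainConfig = TrainConfig(),
                    config: ACOConfig = ACOConfig(),
                    target: str = "od_measured") -> AntSolution:
    """Train a BPNN on the masked calibration features and score the subset.

    Fills cost (BestCost) and the standard chemometrics metrics.  A
    training divergence is recorded as infinite cost: the subset simply
    never wins.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 1:
        raise ValueError("mask must include at least one component")
    X_cal, y_cal = split.xy("calibration", target)
    X_val, y_val = split.xy("validation", target)
    est = BPNNRegressor(
        n_hidden=train_config.n_hidden,
        learning_rate=train_config.learning_rate,
        momentum=train_config.momentum,
        init_weight_scale=train_config.init_weight_scale,
        error_goal=train_config.error_goal,
        max_epochs=train_config.max_epochs,
        random_state=train_config.seed,
    )
    try:
        est.fit(X_cal[:, mask], y_cal)
    except TrainingDivergedError:
        return AntSolution(mask=mask.copy(), cost=float("inf"))
    pred_cal = est.predict(X_cal[:, mask])
    pred_val = est.predict(X_val[:, mask])
    cost = best_cost(y_cal - pred_cal, y_val - pred_val,
                     config.train_weight, config.test_weight)
    metrics = {"Rc2": r2(y_cal, pred_cal), "RMSECV": rmse(y_cal, pred_cal),
               "Rp2": r2(y_val, pred_val), "RMSEP": rmse(y_val, pred_val)}
    return AntSolution(mask=mask.copy(), cost=cost, metrics=metrics)


def deposit_amount(cost: float, Q: float = 1.0) -> float:
    """Ant-cycle deposit Q / cost, guarded against a zero-cost solution."""
    return Q / max(float(cost), _EPS_COST)


def update_pheromone(table: PheromoneTable, solutions: list[AntSolution],
                     config: ACOConfig) -> PheromoneTable:
    """Evaporate, then add every ant's deposit on its chosen states.

    Conventional mode: tau <- (1 - rho) tau + sum_k Q/L_k.
    Literal mode:      tau <- rho tau + sum_k Q/L_k (the printed rule).
    tau is floored at 1e-6 so selection probabilities stay defined.
    """
    rho = config.evaporation
    keep = rho if config.evaporation_mode == "literal" else 1.0 - rho
    table.tau *= keep
    for sol in solutions:
        if not np.isfinite(sol.cost):
            continue
        d = deposit_amount(sol.cost, config.deposit_total)
        idx = np.where(sol.mask, INCLUDE, EXCLUDE)
        table.tau[np.arange(table.tau.shape[0]), idx] += d
    np.maximum(table.tau, _TAU_FLOOR, out=table.tau)
    return table


def run_on_costs(cost_fn, n_components: int, config: ACOConfig,
                 eta: np.ndarray | None = None) -> RunResult:
    """Core ACO loop over an arbitrary subset-cost function.

    ``cost_fn(mask) -> AntSolution`` must be deterministic; the loop
    memoizes it by mask, tracks the best-so-far solution elitistically,
    and returns the full convergence curve.
    """
    rng = np.random.default_rng(config.seed)
    table = PheromoneTable.fresh(n_components, config, eta=eta)
    cache: dict[bytes, AntSolution] = {}
    best: AntSolution | None = None
    curve = np.empty(config.max_iterations)
    convergence_iteration = 0
    for it in range(config.max_iterations):
        solutions = []
        for _ in range(config.n_ants):
            mask = construct_subset(table, config, rng)
            key = mask.tobytes()
            if key not in cache:
                cache[key] = cost_fn(mask)
            sol = cache[key]
            solutions.append(sol)
            if best is None or sol.cost < best.cost - _IMPROVE_TOL:
                best = sol
                convergence_iteration = it
        update_pheromone(table, solutions, config)
        curve[it] = best.cost
    return RunResult(best_solution=best, convergence_curve=curve,
                     convergence_iteration=convergence_iteration,
                     seed=config.seed)


def _visibility(split: SplitDataset, config: ACOConfig,
                n_components: int, target: str) -> np.ndarray | None:
    if config.visibility_mode == "uniform":
        return None
    X, y = split.xy("calibration", target)
    eta = np.ones((n_components, 2))
    for i in range(n_components):
        sd = X[:, i].std()
        c = 0.0 if sd == 0 else abs(float(np.corrcoef(X[:, i], y)[0, 1]))
        eta[i, INCLUDE] = max(c, 0.01)
        eta[i, EXCLUDE] = max(1.0 - c, 0.01)
    return eta


def run(split: SplitDataset, config: ACOConfig = ACOConfig(),
        train_config: TrainConfig = TrainConfig(),
        target: str = "od_measured") -> RunResult:
    """One full wrapper-selection run on a batch-split dataset.

    The BPNN training seed is drawn once from the run seed, so every
    subset evaluation within the run is deterministic and cacheable.
    """
    n_components = split.xy("calibration", target)[0].shape[1]
    seed_rng = np.random.default_rng(config.seed)
    bpnn_seed = int(seed_rng.integers(2 ** 31))
    tc = TrainConfig(
        n_hidden=train_config.n_hidden,
        learning_rate=train_config.learning_rate,
        momentum=train_config.momentum,
        init_weight_scale=train_config.init_weight_scale,
        error_goal=train_config.error_goal,
        max_epochs=train_config.max_epochs,
        seed=bpnn_seed,
    )

    def cost_fn(mask: np.ndarray) -> AntSolution:
        return evaluate_subset(mask, split, tc, config, target)

    eta = _visibility(split, config, n_components, target)
    return run_on_costs(cost_fn, n_components, config, eta=eta)


def repeat_runs(split: SplitDataset, config: ACOConfig = ACOConfig(),
                train_config: TrainConfig = TrainConfig(), n_runs: int = 50,
                base_seed: int = 0, target: str = "od_measured"
                ) -> tuple[list[RunResult], FrequencyTable]:
    """Repeat the optimization from seeds base_seed+1..base_seed+n_runs.

    Returns the per-run results and the per-component tally of how many
    best subsets include each component.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    results = []
    for k in range(1, n_runs + 1):
        cfg = ACOConfig(**{**_config_dict(config), "seed": base_seed + k})
        results.append(run(split, cfg, train_config, target))
    counts = np.sum([res.best_solution.mask for res in results], axis=0)
    return results, FrequencyTable(counts=counts, n_runs=n_runs)


def _config_dict(config: ACOConfig) -> dict:
    return {f: getattr(config, f) for f in config.__dataclass_fields__}


def select_by_frequency(freq: FrequencyTable, threshold: int) -> list[int]:
    """Components selected in at least ``threshold`` runs.

    Ordered by count descending, ties broken by component index.
    """
    if not 0 <= threshold <= freq.n_runs:
        raise ValueError("threshold must lie in [0, n_runs]")
    idx = np.flatnonzero(freq.counts >= threshold)
    order = sorted(idx, key=lambda i: (-int(freq.counts[i]), int(i)))
    return [int(i) for i in order]


class ACOFeatureSelector(SelectorMixin, BaseEstimator):
    """Scikit-learn feature selector wrapping the ACO/BPNN search.

    fit(X, y) splits the rows into an internal calibration/validation
    partition (the last ``validation_fraction`` of rows, or an explicit
    boolean ``calibration_mask`` passed to fit — e.g. a by-batch split),
    runs ``n_runs`` seeded optimizations, and exposes the selected
    support.  With ``frequency_threshold`` set, support is the
    frequency-thresholded component set; otherwise it is the best run's
    subset.
    """

    def __init__(self, n_ants: int = 20, max_iterations: int = 100,
                 n_runs: int = 1, frequency_threshold: int | None = None,
                 evaporation: float = 0.05, deposit_total: float = 1.0,
                 evaporation_mode: str = "conventional",
                 visibility_mode: str = "abs_correlation",
                 validation_fraction: float = 0.25,
                 bpnn_max_epochs: int = 200, bpnn_n_hidden: int = 10,
                 random_state: int | None = None):
        self.n_ants = n_ants
        self.max_iterations = max_iterations
        self.n_runs = n_runs
        self.frequency_threshold = frequency_threshold
        self.evaporation = evaporation
        self.deposit_total = deposit_total
        self.evaporation_mode = evaporation_mode
        self.visibility_mode = visibility_mode
        self.validation_fraction = validation_fraction
        self.bpnn_max_epochs = bpnn_max_epochs
        self.bpnn_n_hidden = bpnn_n_hidden
        self.random_state = random_state

    def fit(self, X, y, calibration_mask: np.ndarray | None = None):
        import pandas as pd

        X, y = check_X_y(X, y, y_numeric=True)
        n = X.shape[0]
        if calibration_mask is None:
            n_cal = max(2, int(round(n * (1 - self.validation_fraction))))
            calibration_mask = np.zeros(n, dtype=bool)
            calibration_mask[:n_cal] = True
        calibration_mask = np.asarray(calibration_mask, dtype=bool)

        cols = [f"f{i}" for i in range(X.shape[1])]
        frame = pd.DataFrame(X, columns=cols)
        frame["target"] = y
        split = SplitDataset(
            calibration=frame[calibration_mask].reset_index(drop=True),
            validation=frame[~calibration_mask].reset_index(drop=True),
            n_cal_batches=0, feature_columns=tuple(cols))

        cfg = ACOConfig(n_ants=self.n_ants, max_iterations=self.max_iterations,
                        evaporation=self.evaporation,
                        deposit_total=self.deposit_total,
                        evaporation_mode=self.evaporation_mode,
                        visibility_mode=self.visibility_mode,
                        seed=self.random_state)
        tc = TrainConfig(n_hidden=self.bpnn_n_hidden,
                         max_epochs=self.bpnn_max_epochs)
        base_seed = 0 if self.random_state is None else int(self.random_state)
        if self.n_runs == 1:
            result = run(split, ACOConfig(**{**_config_dict(cfg),
                                             "seed": base_seed}), tc, "target")
            self.run_results_ = [result]
            self.frequency_ = FrequencyTable(
                counts=result.best_solution.mask.astype(int), n_runs=1)
        else:
            self.run_results_, self.frequency_ = repeat_runs(
                split, cfg, tc, n_runs=self.n_runs, base_seed=base_seed,
                target="target")
        self.best_result_ = min(self.run_results_,
                                key=lambda r: r.best_solution.cost)
        if self.frequency_threshold is not None:
            chosen = select_by_frequency(self.frequency_,
                                         self.frequency_threshold)
            support = np.zeros(X.shape[1], dtype=bool)
            support[chosen] = True
        else:
            support = self.best_result_.best_solution.mask.copy()
        self.support_ = support
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_
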