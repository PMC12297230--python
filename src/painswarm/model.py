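"""Model/Results interface over the swarm-trained classifier.

`SwarmNeuralClassifier` holds data and configuration; `.fit()` runs the
particle swarm over the network's flat parameter vector and returns a
`SwarmNeuralResults` carrying the best parameters, the optimisation
history, held-out metrics and a text `summary()`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from . import metrics as _metrics
from .cohort import CohortTable
from .network import FitnessConfig, NetworkSpec, nll_l2_fitness, predict
from .preprocess import PipelineConfig, SplitBundle, preprocess_region
from .swarm import PSOConfig, SwarmState, carve_validation, pso_train


class SwarmNeuralClassifier:
    """Binary classifier: one hidden ReLU layer trained by particle swarm.

    Parameters
    ----------
    endog : array-like
        Binary labels (0/1) of the training fold.
    exog : array-like
        Training feature matrix (standardised upstream).
    net_spec, fit_cfg : architecture and fitness settings; by default one
        hidden layer of 256 units, softmax output, NLL + L2 (lambda 0.01).
    monitor : optional ``(X, y)`` pair driving early stopping. When omitted,
        a 20% validation slice is carved from the training fold, keeping any
        test data out of the stopping rule.
    """

    def __init__(
        self,
        endog,
        exog,
        net_spec: NetworkSpec | None = None,
        fit_cfg: FitnessConfig | None = None,
        monitor: tuple[np.ndarray, np.ndarray] | None = None,
        feature_names: list[str] | None = None,
    ) -> None:
        self.endog = np.asarray(endog, dtype=int)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or len(self.endog) != len(self.exog):
            raise ValueError("endog/exog shape mismatch")
        self.net_spec = net_spec or NetworkSpec(n_input=self.exog.shape[1])
        if self.net_spec.n_input != self.exog.shape[1]:
            raise ValueError("net_spec.n_input does not match exog")
        self.fit_cfg = fit_cfg or FitnessConfig()
        self.monitor = monitor
        self.feature_names = feature_names or [
            f"x{i}" for i in range(self.exog.shape[1])
        ]

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_bundle(
        cls,
        bundle: SplitBundle,
        net_spec: NetworkSpec | None = None,
        fit_cfg: FitnessConfig | None = None,
        monitor_on_test: bool = False,
    ) -> "SwarmNeuralClassifier":
        """Build from a preprocessed split.

        ``monitor_on_test=True`` reproduces the published stopping rule
        (loss watched on the test fold); the default keeps the test fold out
        of training entirely.
        """
        monitor = (bundle.X_test, bundle.y_test) if monitor_on_test else None
        model = cls(
            bundle.y_train,
            bundle.X_train,
            net_spec=net_spec,
            fit_cfg=fit_cfg,
            monitor=monitor,
            feature_names=bundle.feature_names,
        )
        model._bundle = bundle
        return model

    @classmethod
    def from_cohort(
        cls,
        table: CohortTable,
        region: str,
        pipeline_cfg: PipelineConfig | None = None,
        net_spec: NetworkSpec | None = None,
        fit_cfg: FitnessConfig | None = None,
        monitor_on_test: bool = False,
    ) -> "SwarmNeuralClassifier":
        """Preprocess one region's current-pain outcome and build the model."""
        bundle = preprocess_region(table, region, pipeline_cfg)
        if net_spec is None:
            net_spec = NetworkSpec(n_input=bundle.X_train.shape[1])
        return cls.from_bundle(
            bundle, net_spec=net_spec, fit_cfg=fit_cfg, monitor_on_test=monitor_on_test
        )

    # -- fitting -----------------------------------------------------------
    def fit(self, pso_cfg: PSOConfig | None = None) -> "SwarmNeuralResults":
        pso_cfg = pso_cfg or PSOConfig()
        if self.monitor is not None:
            train = (self.exog, self.endog)
            monitor = self.monitor
        else:
            train, monitor = carve_validation(
                self.exog, self.endog, fraction=0.2, seed=pso_cfg.seed
            )
        params, state = pso_train(
            train, monitor, self.net_spec, self.fit_cfg, pso_cfg
        )
        return SwarmNeuralResults(self, params, state, pso_cfg)


@dataclass
class SwarmNeuralResults:
    """Fit outcome: best parameter vector, swarm history, diagnostics."""

    model: SwarmNeuralClassifier
    params: np.ndarray
    swarm_state: SwarmState
    pso_cfg: PSOConfig
    _cache: dict = field(default_factory=dict, repr=False)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_epochs(self) -> int:
        return self.swarm_state.epoch

    @property
    def stop_reason(self) -> str:
        return self.swarm_state.stop_reason

    @property
    def final_fitness(self) -> float:
        return self.swarm_state.gbest_fitness

    def train_fitness(self) -> float:
        return nll_l2_fitness(
            self.params,
            self.model.exog,
            self.model.endog,
            self.model.fit_cfg,
            self.model.net_spec,
        )

    # -- prediction and evaluation -----------------------------------------
    def predict(self, X) -> np.ndarray:
        labels, _ = predict(np.asarray(X, dtype=float), self.params, self.model.net_spec)
        return labels

    def predict_proba(self, X) -> np.ndarray:
        _, p1 = predict(np.asarray(X, dtype=float), self.params, self.model.net_spec)
        return p1

    def evaluate(self, X, y) -> dict:
        """Accuracy, macro PRF, AUC, confusion matrix and ROC points on (X, y)."""
        y = np.asarray(y, dtype=int)
        labels = self.predict(X)
        scores = self.predict_proba(X)
        cm = _metrics.confusion_matrix(y, labels)
        out = _metrics.classification_metrics(cm)
        auc, roc_points = _metrics.roc_auc(y, scores)
        out.update(
            auc=auc, confusion=cm, roc_points=roc_points, n_test=len(y)
        )
        return out

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        spec = self.model.net_spec
        lines = [
            "Swarm-trained neural classifier",
            "=" * 46,
            f"{'architecture':24s} {spec.n_input}-{spec.n_hidden}-{spec.n_output} (ReLU, softmax)",
            f"{'parameters':24s} {spec.n_parameters}",
            f"{'L2 lambda':24s} {self.model.fit_cfg.l2_lambda}",
            f"{'particles':24s} {self.pso_cfg.n_particles}",
            f"{'inertia mode':24s} {self.pso_cfg.w_mode}",
            f"{'c1 / c2':24s} {self.pso_cfg.c1} / {self.pso_cfg.c2}",
            f"{'v_max':24s} {self.pso_cfg.v_max}",
            f"{'seed':24s} {self.pso_cfg.seed}",
            f"{'epochs run':24s} {self.n_epochs}",
            f"{'stop reason':24s} {self.stop_reason}",
            f"{'best train fitness':24s} {self.final_fitness:.6f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def fingerprint(self) -> dict:
        """Everything needed to replay this fit deterministically."""
        return {
            "pso_cfg": asdict(self.pso_cfg),
            "fit_cfg": asdict(self.model.fit_cfg),
            "net_spec": asdict(self.model.net_spec),
        }

    # -- plotting ----------------------------------------------------------
    def plot_history(self, ax=None):
        """Training fitness and monitored loss per epoch."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        rows = self.swarm_state.history_rows()
        epochs = [r[0] for r in rows]
        ax.plot(epochs, [r[2] for r in rows], label="gbest train fitness")
        ax.plot(epochs, [r[3] for r in rows], label="monitored loss")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax.legend()
        return ax

    def plot_roc(self, X, y, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        report = self.evaluate(X, y)
        fpr, tpr = zip(*report["roc_points"])
        ax.plot(fpr, tpr, marker=".")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"AUC = {report['auc']:.3f}")
        return ax
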