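"""Model/Results interface tying the pipeline together.

:class:`SolubilityModel` is built from solubility records plus a
sigma-potential grid library; :meth:`SolubilityModel.fit` runs feature
selection and the learning-curve-penalised hyperparameter search and
returns a :class:`SolubilityResults` carrying the fitted estimator, the
selected descriptors, train/CV/test metrics and the learning curve,
with ``summary()``, ``predict()`` and plotting attached.

Example
-------
>>> from dessol import synthetic, model
>>> cfg = synthetic.GeneratorConfig(seed=1)
>>> records = synthetic.generate_corpus(cfg)
>>> grids = [synthetic.generate_sigma_grid(cfg, c, t)
...          for c in synthetic.DEFAULT_SHAPES
...          for t in (278.15, 298.15, 323.15)]
>>> m = model.SolubilityModel(records, grids)
>>> res = m.fit(family="ridge", n_trials=5, seed=0)
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import search as _search
from .data import SolubilityRecord
from .search import (
    FINAL_FRACTIONS,
    TUNING_FRACTIONS,
    LearningCurve,
    MetricSet,
    ModelSearchResult,
    compute_metrics,
    learning_curve_analysis,
    split_train_test,
    tune,
)
from .sigma import (
    SIGMA_GRID,
    DescriptorVector,
    SigmaGrid,
    SigmaRegionPartition,
    partition_regions,
    relative_potential,
    select_features,
)
from .thermo import FusionProperties, ideal_solubility

__all__ = ["SolubilityModel", "SolubilityResults"]


class SolubilityModel:
    """Sigma-potential QSPR model of mole-fraction solubility.

    Parameters
    ----------
    records
        Validated solubility records (the response is log10 of the
        mole-fraction solubility).
    grids
        Pure-compound sigma-potential grids covering every solvent
        component and the solute at (or bracketing) each record's
        temperature.
    solute_id
        Compound id of the solute within ``grids``.
    partition
        Sigma-axis region partition used for reporting selected
        descriptors per chemical band.
    threshold
        R^2 threshold of the per-sigma-point feature selection.
    fusion, dcp_mode
        When fusion properties are given, the ideal solid-liquid
        equilibrium solubility at each record's temperature is appended
        as an extra descriptor (log10 scale).
    """

    def __init__(
        self,
        records: Sequence[SolubilityRecord],
        grids: Sequence[SigmaGrid],
        solute_id: str = "FA",
        partition: SigmaRegionPartition | None = None,
        threshold: float = 0.4,
        fusion: FusionProperties | None = None,
        dcp_mode: str = "zero",
    ):
        self.records = list(records)
        if not self.records:
            raise ValueError("no records")
        self.grids = list(grids)
        self.solute_id = solute_id
        self.partition = partition or SigmaRegionPartition()
        self.threshold = threshold
        self.fusion = fusion
        self.dcp_mode = dcp_mode
        self._descriptors: list[DescriptorVector] | None = None

    @classmethod
    def from_dataframe(cls, df, grids, **kwargs) -> "SolubilityModel":
        """Build from the solubility CSV layout (see :mod:`dessol.data`)."""
        from .data import frame_to_records

        return cls(frame_to_records(df), grids, **kwargs)

    # -- design matrix ----------------------------------------------------

    def descriptors(self) -> list[DescriptorVector]:
        """Relative sigma-potential descriptors for every record (cached)."""
        if self._descriptors is None:
            out = []
            for r in self.records:
                solute = _solute_grid(
                    self.grids, self.solute_id, r.temperature
                )
                extra = None
                if self.fusion is not None:
                    extra = float(np.log10(ideal_solubility(
                        self.fusion, r.temperature, dcp_mode=self.dcp_mode
                    )))
                out.append(relative_potential(
                    solute, r.system, self.grids, r.temperature,
                    record_id=r.record_id, extra=extra,
                ))
            self._descriptors = out
        return self._descriptors

    @property
    def endog(self) -> np.ndarray:
        """log10 mole-fraction solubility of every record."""
        return np.log10([r.x_solubility for r in self.records])

    def feature_mask(self) -> np.ndarray:
        """Boolean sigma-point selection mask (subset-wise R^2 threshold)."""
        return select_features(
            self.descriptors(), self.endog,
            [r.class_tag for r in self.records], self.threshold,
        )

    def design_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Selected relative-potential columns (+ SLE descriptor if set)."""
        mask = self.feature_mask() if mask is None else np.asarray(mask, bool)
        desc = self.descriptors()
        X = np.vstack([d.relative_mu for d in desc])[:, mask]
        if self.fusion is not None:
            extra = np.array([[d.extra] for d in desc])
            X = np.hstack([X, extra])
        return X

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        family: str = "svr",
        n_trials: int = 100,
        sampler=None,
        seed: int = 0,
        fraction_train: float = 2.0 / 3.0,
        k_folds: int = 10,
        final_curve: bool = False,
    ) -> "SolubilityResults":
        """Tune and fit one model family; return the results object.

        The records are split 2:1 (stratified by provenance class), the
        LCA-penalised search runs on the training partition, and the
        best estimator is refit on it.  ``final_curve=True`` additionally
        computes the 20-point diagnostic learning curve.
        """
        mask = self.feature_mask()
        X = self.design_matrix(mask)
        y = self.endog
        ids = np.arange(len(self.records))
        tags = [r.class_tag for r in self.records]
        train_ids, test_ids = split_train_test(
            ids, tags, fraction_train=fraction_train, seed=seed
        )
        tr = np.asarray(train_ids, dtype=int)
        te = np.asarray(test_ids, dtype=int)
        result = tune(
            family, X[tr], y[tr], n_trials=n_trials, sampler=sampler,
            seed=seed, k_folds=k_folds,
        )
        est = _search.build_estimator(family, result.best_params)
        est.fit(X[tr], y[tr])
        test_metrics = (
            compute_metrics(y[te], est.predict(X[te])) if len(te) else None
        )
        pooled_metrics = compute_metrics(y, est.predict(X))
        final = None
        if final_curve:
            final = learning_curve_analysis(
                _search.build_estimator(family, result.best_params),
                X[tr], y[tr], fractions=FINAL_FRACTIONS,
                k_folds=k_folds, seed=seed,
            )
        return SolubilityResults(
            model=self,
            search=result,
            estimator=est,
            mask=mask,
            train_idx=tr,
            test_idx=te,
            test_metrics=test_metrics,
            pooled_metrics=pooled_metrics,
            final_curve=final,
        )


def _solute_grid(grids, solute_id, temperature):
    from .sigma import lookup_grid

    return lookup_grid(grids, solute_id, temperature)


@dataclass
class SolubilityResults:
    """Fitted solubility model with diagnostics.

    ``train_metrics``/``cv_metrics`` come from the search (training
    partition); ``test_metrics`` from the held-out third;
    ``pooled_metrics`` from back-computing the whole dataset, which is
    how headline accuracy figures are usually quoted and therefore
    labelled explicitly here.
    """

    model: SolubilityModel
    search: ModelSearchResult
    estimator: object
    mask: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    test_metrics: MetricSet | None
    pooled_metrics: MetricSet
    final_curve: LearningCurve | None = None

    @property
    def family_id(self) -> str:
        return self.search.family_id

    @property
    def train_metrics(self) -> MetricSet:
        return self.search.train_metrics

    @property
    def cv_metrics(self) -> MetricSet:
        return self.search.cv_metrics

    def predict(self, records: Sequence[SolubilityRecord]) -> np.ndarray:
        """Predicted mole-fraction solubility for new records."""
        sub = SolubilityModel(
            records, self.model.grids, self.model.solute_id,
            self.model.partition, self.model.threshold,
            self.model.fusion, self.model.dcp_mode,
        )
        X = sub.design_matrix(self.mask)
        log10x = self.estimator.predict(X)
        return 10.0 ** np.clip(log10x, -12.0, 0.0)

    def selected_regions(self) -> dict[str, list[int]]:
        """Selected sigma indices per HBD/HYD/HBA band."""
        return partition_regions(self.model.partition, self.mask)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = []
        add = lines.append
        add("Sigma-potential solubility model")
        add("=" * 48)
        add(f"family:            {self.family_id}")
        add(f"records:           {len(self.model.records)} "
            f"(train {len(self.train_idx)}, test {len(self.test_idx)})")
        counts = {k: len(v) for k, v in self.selected_regions().items()}
        add(f"selected features: {int(self.mask.sum())} of {len(self.mask)} "
            f"sigma points (HBD {counts['HBD']}, HYD {counts['HYD']}, "
            f"HBA {counts['HBA']})"
            + (" + SLE descriptor" if self.model.fusion is not None else ""))
        add(f"search score:      {self.search.score:.4f} "
            f"(LCA penalty {self.search.penalty:.4f}, "
            f"{self.search.n_trials} trials, seed {self.search.seed})")
        add("")
        add(f"{'metrics (log10 x)':<20}{'MAE':>8}{'RMSD':>8}"
            f"{'MAPE%':>8}{'R2':>8}")

        def row(name, m):
            if m is None:
                add(f"{name:<20}{'-':>8}{'-':>8}{'-':>8}{'-':>8}")
            else:
                r2 = f"{m.r2:.3f}" if m.r2 is not None else "-"
                add(f"{name:<20}{m.mae:>8.4f}{m.rmsd:>8.4f}"
                    f"{m.mape_percent:>8.2f}{r2:>8}")

        row("train", self.train_metrics)
        row("cv (train part.)", self.cv_metrics)
        row("test", self.test_metrics)
        row("pooled", self.pooled_metrics)
        add("")
        add("best hyperparameters:")
        for k, v in self.search.best_params.items():
            add(f"  {k} = {v}")
        return "\n".join(lines)

    def plot_learning_curve(self, ax=None):
        """Train/CV MAE versus data fraction (final curve if computed)."""
        import matplotlib.pyplot as plt

        curve = self.final_curve or self.search.lca
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve.fractions, curve.train_mae, "o-", label="train MAE")
        ax.plot(curve.fractions, curve.cv_mae, "s-", label="CV MAE")
        ax.set_xlabel("data fraction")
        ax.set_ylabel("MAE (log10 x)")
        ax.set_title(f"learning curve — {self.family_id}")
        ax.legend()
        return ax
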