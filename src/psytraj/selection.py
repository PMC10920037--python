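"""Hyperparameter grid search and choice of K by prediction strength.

Prediction strength asks how reproducible a K-cluster solution is: split
the participants in half, cluster each half independently, and check, for
each cluster of the test half, what fraction of its within-cluster pairs
the model trained on the *other* half also places together.  The statistic
is the minimum of that fraction over test clusters; values near 1 mean the
clustering replicates, values near 1/K mean it does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import spawn_seed
from .preprocessing import TrajectoryTensor
from .vader import VaderConfig, assign, fit, loss_terms, pretrain


@dataclass
class GridSearchResult:
    table: pd.DataFrame  # one row per configuration: mean/sd validation loss
    excluded: list[tuple[dict, str]]
    selected: VaderConfig | None


@dataclass
class PredictionStrengthCurve:
    per_repeat: dict[int, np.ndarray] = field(default_factory=dict)
    occupancy: dict[int, float] = field(default_factory=dict)

    def add(self, k: int, values: np.ndarray, occupied_fraction: float = 1.0):
        self.per_repeat[int(k)] = np.asarray(values, float)
        self.occupancy[int(k)] = float(occupied_fraction)

    @property
    def entries(self) -> pd.DataFrame:
        rows = [{"k": k, "mean": v.mean(),
                 "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
                 "occupied_fraction": self.occupancy.get(k, 1.0)}
                for k, v in self.per_repeat.items()]
        return pd.DataFrame(rows, columns=["k", "mean", "sd", "occupied_fraction"])


def pair_coassignment_strength(test_labels: np.ndarray,
                               reference_labels: np.ndarray) -> float:
    """Minimum over test clusters of the co-assigned within-pair fraction.

    For each test cluster j with n_j >= 2, count the ordered pairs
    (i, i') of its members that the reference labeling puts in a common
    cluster, divided by n_j (n_j − 1).  Clusters of size < 2 contribute no
    pairs; with no scorable cluster the statistic is 1 by convention
    (nothing to contradict).
    """
    test_labels = np.asarray(test_labels)
    reference_labels = np.asarray(reference_labels)
    if test_labels.shape != reference_labels.shape:
        raise ValueError("label vectors differ in length")
    fractions = []
    for j in np.unique(test_labels):
        members = reference_labels[test_labels == j]
        n_j = len(members)
        if n_j < 2:
            continue
        _, counts = np.unique(members, return_counts=True)
        co = (counts * (counts - 1)).sum()
        fractions.append(co / (n_j * (n_j - 1)))
    return float(min(fractions)) if fractions else 1.0


def _scaled(config: VaderConfig, epoch_factor: float, seed: int) -> VaderConfig:
    return replace(config,
                   epochs=max(1, int(round(config.epochs * epoch_factor))),
                   pretrain_epochs=max(1, int(round(config.pretrain_epochs * epoch_factor))),
                   seed=seed)


def prediction_strength(data: TrajectoryTensor, k: int, config: VaderConfig,
                        repeats: int = 20, seed: int = 0,
                        epoch_factor: float = 1.0,
                        with_occupancy: bool = False):
    """Per-repeat prediction strength of the K-cluster model under 2-fold CV.

    Each repeat halves the participants at random, trains one model per
    half at ``epoch_factor``-scaled epochs, scores each half's own clusters
    against the other half's model, and averages the two role-swapped
    values.  K = 1 is 1 by definition (a single cluster co-assigns every
    pair).

    With ``with_occupancy`` the fraction of trained half-models whose own
    assignment occupies all K components is returned alongside the values:
    a "K-cluster" model with empty components behaves like a smaller model
    and replicates deceptively well, so the fraction qualifies the curve.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if data.n < 4:
        raise ValueError("need at least 4 participants")
    if k == 1:
        return (np.ones(repeats), 1.0) if with_occupancy else np.ones(repeats)
    values = np.empty(repeats)
    full = 0
    rng = np.random.default_rng(spawn_seed(seed, 11))
    for r in range(repeats):
        order = rng.permutation(data.n)
        half_a, half_b = order[: data.n // 2], order[data.n // 2:]
        if min(len(half_a), len(half_b)) < k:
            raise ValueError(f"a half has fewer than k={k} participants")
        sub = {"A": data.subset(half_a), "B": data.subset(half_b)}
        models = {}
        for name, s in sub.items():
            cfg = _scaled(replace(config, k=k), epoch_factor,
                          spawn_seed(seed, 13, r, ord(name)))
            models[name], _ = fit(s, cfg)
        own_a = assign(models["A"], sub["A"]).labels
        own_b = assign(models["B"], sub["B"]).labels
        ps_ab = pair_coassignment_strength(
            own_b, assign(models["A"], sub["B"]).labels)
        ps_ba = pair_coassignment_strength(
            own_a, assign(models["B"], sub["A"]).labels)
        values[r] = 0.5 * (ps_ab + ps_ba)
        full += int(len(np.unique(own_a)) == k) + int(len(np.unique(own_b)) == k)
    if with_occupancy:
        return values, full / (2 * repeats)
    return values


def prediction_strength_curve(data: TrajectoryTensor, k_values, config: VaderConfig,
                              repeats: int = 20, seed: int = 0,
                              epoch_factor: float = 1.0) -> PredictionStrengthCurve:
    curve = PredictionStrengthCurve()
    for k in k_values:
        values, occ = prediction_strength(data, k, config, repeats=repeats,
                                          seed=spawn_seed(seed, 17, k),
                                          epoch_factor=epoch_factor,
                                          with_occupancy=True)
        curve.add(k, values, occupied_fraction=occ)
    return curve


def choose_k(curve: PredictionStrengthCurve, threshold: float = 0.8,
             occupancy_threshold: float = 0.5) -> int:
    """Largest K with mean prediction strength >= threshold, else 1.

    A candidate K is only eligible when at least ``occupancy_threshold`` of
    its trained models occupied all K components: models that leave
    components empty are effectively smaller-K solutions and replicate
    deceptively well (the same exclusion logic the hyperparameter grid
    search applies).  Curves built without occupancy information treat
    every K as fully occupied.
    """
    entries = curve.entries
    if len(entries) == 0:
        raise ValueError("empty prediction-strength curve")
    ok = entries.loc[(entries["mean"] >= threshold)
                     & (entries["occupied_fraction"] >= occupancy_threshold), "k"]
    return int(ok.max()) if len(ok) else 1


# ---------------------------------------------------------------------------
# hyperparameter grid search
# ---------------------------------------------------------------------------


def _validation_loss(config: VaderConfig, train: TrajectoryTensor,
                     valid: TrajectoryTensor, epoch_factor: float, seed: int) -> float:
    """Reconstruction-only training at K=1; masked MSE on the held-out fold."""
    cfg = _scaled(replace(config, k=1), epoch_factor, seed)
    cfg = replace(cfg, pretrain_epochs=max(cfg.pretrain_epochs, cfg.epochs))
    model, _ = pretrain(train, cfg)
    recon, _ = loss_terms(model, valid.values, valid.mask, eps=None)
    return float(recon.data)


def grid_search(data: TrajectoryTensor, grid: list[VaderConfig], target_k: int,
                folds: int = 10, repeats: int = 20, seed: int = 0,
                epoch_factor: float = 1.0) -> GridSearchResult:
    """Repeated k-fold CV of reconstruction loss over a configuration grid.

    Each configuration is trained with one cluster and the reconstruction
    loss only, scored on held-out folds over ``folds`` × ``repeats``
    splits.  Configurations that, refit at ``target_k`` on the full data,
    produce fewer than ``target_k`` non-empty clusters are excluded.  The
    surviving configuration with minimal mean validation loss is selected;
    ties break on the configuration's canonical text so the result does not
    depend on grid order.
    """
    if not grid:
        raise ValueError("empty grid")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rows = []
    excluded: list[tuple[dict, str]] = []
    for config in grid:
        losses = []
        for rep in range(repeats):
            rng = np.random.default_rng(spawn_seed(seed, 19, rep))
            order = rng.permutation(data.n)
            fold_ids = np.arange(data.n) % folds
            for f in range(folds):
                valid_idx = order[fold_ids == f]
                train_idx = order[fold_ids != f]
                losses.append(_validation_loss(
                    config, data.subset(train_idx), data.subset(valid_idx),
                    epoch_factor, spawn_seed(seed, 23, rep, f)))
        mean_loss = float(np.mean(losses))
        # exclusion check: does the configuration sustain target_k clusters?
        cfg_full = _scaled(replace(config, k=target_k), epoch_factor,
                           spawn_seed(seed, 29))
        model, _ = fit(data, cfg_full)
        n_nonempty = len(np.unique(assign(model, data).labels))
        row = {"config": config, "mean_loss": mean_loss,
               "sd_loss": float(np.std(losses, ddof=1)) if len(losses) > 1 else 0.0,
               "n_nonempty": n_nonempty}
        rows.append(row)
        if n_nonempty < target_k:
            excluded.append((vars(config).copy(),
                             f"collapsed to {n_nonempty} < {target_k} clusters"))
    table = pd.DataFrame([{**{k: v for k, v in vars(r["config"]).items()},
                           "mean_loss": r["mean_loss"], "sd_loss": r["sd_loss"],
                           "n_nonempty": r["n_nonempty"]} for r in rows])
    survivors = [r for r in rows if r["n_nonempty"] >= target_k]
    if not survivors:
        return GridSearchResult(table, excluded, None)
    selected = min(survivors, key=lambda r: (r["mean_loss"], repr(sorted(vars(r["config"]).items()))))
    return GridSearchResult(table, excluded, selected["config"])
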