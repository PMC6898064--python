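"""End-to-end orchestration: splitting, evaluation, sweeps, latent embedding.

Everything here is a thin, reproducible composition of the other modules:
each function is deterministic given its explicit seed, so re-running a
pipeline stage from the same configuration reproduces identical splits,
curves and embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .closure import (MaterialProperties, SimulationCondition, ValveDataset,
                      coaptation_from_displacements, simulate_closure)
from .design import ValveDesignParams, build_valve
from .metrics import (MetricsReport, coaptation_stats, hausdorff,
                      mean_euclidean, procrustes, surface_point_cloud)
from .model import ClosureSurrogate, SurrogateConfig, train

__all__ = [
    "SplitSpec",
    "SweepSpec",
    "split_dataset",
    "evaluate_run",
    "parameter_sweep",
    "tsne_embed",
    "quartile_knn_accuracy",
    "run_experiment",
]

MATERIAL_FIELDS = ("c0", "c1", "c2", "thickness")


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions; train and validation sizes are
    rounded to the nearest integer, the test set takes the remainder."""

    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(f < 0 for f in self.fractions):
            raise ValueError("need three non-negative fractions")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(self.fractions)}")


def split_dataset(n_total: int, spec: SplitSpec = SplitSpec()) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shuffled disjoint exhaustive partition of range(n_total)."""
    if n_total < 3:
        raise ValueError("need at least 3 samples to split")
    f_train, f_val, _ = spec.fractions
    n_train = int(round(f_train * n_total))
    n_val = int(round(f_val * n_total))
    if n_train + n_val > n_total:
        raise ValueError("rounded train+validation exceed the corpus")
    perm = np.random.default_rng(spec.seed).permutation(n_total)
    return perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:]


def evaluate_run(model: ClosureSurrogate, dataset: ValveDataset, indices,
                 hausdorff_sampling: tuple[int, int] = (50, 50),
                 csv_path=None) -> tuple[MetricsReport, pd.DataFrame]:
    """Per-valve shape metrics and corpus aggregates on a split.

    For each valve the predicted deformed configuration (reference control
    points + predicted displacements) is compared with the true one by mean
    Euclidean distance on control points, symmetric Hausdorff distance on
    dense surface samples, and partial Procrustes RMSD on control points.
    Coaptation statistics (RMSE, Pearson R) compare the coaptation head's
    predictions with the simulated areas.
    """
    indices = np.asarray(indices)
    if len(indices) == 0:
        raise ValueError("empty evaluation split")
    pred = model.predict(dataset, indices)
    rows = []
    for row, idx in enumerate(indices):
        valve = dataset.valve_at(idx)
        ref = dataset.reference[idx]
        true_pos = ref + dataset.displacement[idx]
        pred_pos = ref + pred.displacement[row]
        true_surf = [lf.with_control_points(true_pos[k])
                     for k, lf in enumerate(valve.leaflets)]
        pred_surf = [lf.with_control_points(pred_pos[k])
                     for k, lf in enumerate(valve.leaflets)]
        rows.append({
            "index": int(idx),
            "euclidean": mean_euclidean(pred_pos, true_pos),
            "hausdorff": hausdorff(surface_point_cloud(pred_surf, hausdorff_sampling),
                                   surface_point_cloud(true_surf, hausdorff_sampling)),
            "procrustes": procrustes(pred_pos, true_pos),
            "coaptation_true": dataset.coaptation[idx],
            "coaptation_pred": float(pred.coaptation_area[row]),
        })
    table = pd.DataFrame(rows)
    rmse, r = coaptation_stats(table["coaptation_pred"].to_numpy(),
                               table["coaptation_true"].to_numpy())
    report = MetricsReport(
        euclidean=MetricsReport.aggregate(table["euclidean"].to_numpy()),
        hausdorff=MetricsReport.aggregate(table["hausdorff"].to_numpy()),
        procrustes=MetricsReport.aggregate(table["procrustes"].to_numpy()),
        coaptation_rmse=rmse, coaptation_r=r, n_valves=len(table))
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    return report, table


@dataclass(frozen=True)
class SweepSpec:
    """Dense one-parameter sweep: every other input held fixed."""

    parameter: str
    low: float
    high: float
    n_points: int = 1000
    design: ValveDesignParams = ValveDesignParams()
    material: MaterialProperties = MaterialProperties(400.0, 200.0, 1.0, 0.05)
    pressure: float = 80.0
    n_spot_checks: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a sweep needs at least 2 points")
        valid = ("pressure",) + MATERIAL_FIELDS + ValveDesignParams.FIELDS
        if self.parameter not in valid:
            raise ValueError(f"unknown sweep parameter {self.parameter!r}; "
                             f"expected one of {valid}")


def _sweep_inputs(spec: SweepSpec, value: float):
    """(design, material, pressure) with the swept parameter set to value."""
    design, material, pressure = spec.design, spec.material, spec.pressure
    if spec.parameter == "pressure":
        pressure = value
    elif spec.parameter in MATERIAL_FIELDS:
        material = replace(material, **{spec.parameter: value})
    else:
        design = replace(design, **{spec.parameter: value})
    return design, material, pressure


def parameter_sweep(model: ClosureSurrogate, spec: SweepSpec) -> pd.DataFrame:
    """Predicted coaptation-area curve along one parameter.

    Returns a DataFrame with columns ``value`` and ``coaptation_pred``; with
    ``n_spot_checks > 0``, surrogate simulations at random sweep values add
    ``coaptation_sim`` spot checks (NaN elsewhere) — the analogue of overlaying
    simulated points on the densely predicted curve with a +-10% band.
    """
    cfg = model.config
    values = np.linspace(spec.low, spec.high, spec.n_points)
    textures, mats, press = [], [], []
    for val in values:
        design, material, pressure = _sweep_inputs(spec, val)
        valve = build_valve(design, grid=cfg.grid)
        textures.append(valve.textures())
        mats.append(material.as_array())
        press.append(pressure)
    textures = np.asarray(textures)
    mats = model.standardizer.material(np.asarray(mats))
    press_vec = model.standardizer.pressure_vector(np.asarray(press), cfg.pressure_repeat)
    preds = []
    for start in range(0, len(values), 256):
        bundle = model.forward(textures[start:start + 256], mats[start:start + 256],
                               press_vec[start:start + 256])
        preds.append(bundle.coaptation_area)
    table = pd.DataFrame({"value": values, "coaptation_pred": np.concatenate(preds)})
    if spec.n_spot_checks > 0:
        rng = np.random.default_rng(spec.seed)
        spots = rng.choice(spec.n_points, size=spec.n_spot_checks, replace=False)
        sim = np.full(spec.n_points, np.nan)
        for pos in spots:
            design, material, pressure = _sweep_inputs(spec, values[pos])
            valve = build_valve(design, grid=cfg.grid)
            deformed = simulate_closure(valve, material, SimulationCondition(pressure),
                                        noise_seed=int(rng.integers(2**31)))
            sim[pos] = deformed.coaptation_area
        table["coaptation_sim"] = sim
    return table


def spot_check_band_fraction(sweep_table: pd.DataFrame, band: float = 0.10) -> float:
    """Fraction of simulated spot checks within ``band`` (relative) of the
    predicted curve."""
    if "coaptation_sim" not in sweep_table:
        raise ValueError("sweep has no spot checks")
    spots = sweep_table.dropna(subset=["coaptation_sim"])
    if len(spots) == 0:
        raise ValueError("sweep has no spot checks")
    rel = np.abs(spots["coaptation_sim"] - spots["coaptation_pred"]) \
        / np.abs(spots["coaptation_pred"])
    return float(np.mean(rel <= band))


def tsne_embed(codes: np.ndarray, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """Seeded 2D t-SNE embedding of code-layer vectors.

    Design-parameter labels are used only for coloring downstream, never as
    input to the embedding.
    """
    from sklearn.manifold import TSNE
    codes = np.asarray(codes, float)
    if len(codes) < 50:
        raise ValueError("need at least 50 code vectors for a stable embedding")
    if perplexity >= len(codes):
        raise ValueError("perplexity must be below the number of samples")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(codes)


def quartile_knn_accuracy(embedding: np.ndarray, values: np.ndarray,
                          n_neighbors: int = 5, seed: int = 0) -> float:
    """Cross-validated accuracy of a k-NN classifier predicting the
    quartile-binned parameter from the 2D embedding (chance = 0.25)."""
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.neighbors import KNeighborsClassifier
    values = np.asarray(values, float)
    bins = np.quantile(values, [0.25, 0.5, 0.75])
    labels = np.digitize(values, bins)
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    scores = cross_val_score(KNeighborsClassifier(n_neighbors=n_neighbors),
                             np.asarray(embedding, float), labels, cv=cv)
    return float(np.mean(scores))


def run_experiment(seed: int = 0, n_samples: int = 2000,
                   config: SurrogateConfig | None = None,
                   split: SplitSpec | None = None,
                   generate_kwargs: dict | None = None,
                   verbose: bool = False) -> dict:
    """Generate a corpus, split it, train the surrogate and evaluate it.

    One seed drives dataset generation, splitting, initialization and
    shuffling, so the whole experiment is reproducible end to end.  Returns a
    dict with the dataset, split indices, model, history, metrics report and
    per-valve table.
    """
    from .closure import generate_dataset
    ss = np.random.SeedSequence(seed)
    s_data, s_split, s_model = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    dataset = generate_dataset(n_samples, seed=s_data, **(generate_kwargs or {}))
    split = split or SplitSpec(seed=s_split)
    train_idx, val_idx, test_idx = split_dataset(len(dataset), split)
    cfg = config or SurrogateConfig(grid=dataset.grid, seed=s_model)
    model, history = train(dataset, train_idx, val_idx, cfg, verbose=verbose)
    report, table = evaluate_run(model, dataset, test_idx)
    return {"dataset": dataset, "splits": (train_idx, val_idx, test_idx),
            "model": model, "history": history, "report": report, "table": table}
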