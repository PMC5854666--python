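"""Ensemble ecological niche models: training sets, members, consensus.

Per species: build presence / pseudo-absence training sets (prevalence 0.5,
pseudo-absences drawn outside a spatial buffer around presences, repeated R
times; tree-type species use their recorded real absences instead), fit a
committee of model families, evaluate each member by AUC on a stratified
holdout, form an AUC-weighted consensus suitability surface for each period,
and binarize it at the max-TSS threshold.

The default committee spans four learner shapes — regularized logistic
regression with quadratic terms, a recursive-partitioning tree, bagged
trees, and k-nearest neighbours — each emitting a per-cell probability.
The registry is pluggable so users can add families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .grid import LandscapeGrid
from .predictors import PredictorSet
from .synthetic import (FUTURE, N_DEPOSIT_CLASSES, N_DRAINAGE_CLASSES,
                        PERIODS, REFERENCE, ClimateScenario)

log = logging.getLogger(__name__)

DEFAULT_FAMILIES = ("glm_quadratic", "cart", "bagged_trees", "knn")
DEFAULT_N_REPETITIONS = 10
DEFAULT_BUFFER_CELLS = 2.0   # buffer radius in cell widths
DEFAULT_AUC_FLOOR = 0.7
DEFAULT_CALIBRATION_FRACTION = 0.7


class SpeciesSkipped(Exception):
    """Species cannot be modelled (degenerate data); logged and skipped."""


def _make_family(name: str, seed: int):
    if name == "glm_quadratic":
        return Pipeline([
            ("scale", StandardScaler()),
            ("poly", PolynomialFeatures(degree=2, include_bias=False)),
            ("clf", LogisticRegression(C=1.0, max_iter=1000)),
        ])
    if name == "cart":
        return DecisionTreeClassifier(max_depth=6, min_samples_leaf=5,
                                      random_state=seed)
    if name == "bagged_trees":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(min_samples_leaf=3),
            n_estimators=40, random_state=seed)
    if name == "knn":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", KNeighborsClassifier()),  # n_neighbors set at fit time
        ])
    raise ValueError(f"unknown model family {name!r}")


MODEL_FAMILIES: dict[str, object] = {name: _make_family
                                     for name in DEFAULT_FAMILIES}


def register_family(name: str, factory) -> None:
    """Add a model family: factory(name, seed) -> sklearn-like estimator."""
    MODEL_FAMILIES[name] = factory


# ---------------------------------------------------------------------------
# training sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingSet:
    species_id: str
    repetition: int
    cell_ids: np.ndarray
    labels: np.ndarray  # 1 presence, 0 (pseudo-)absence

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean())


def select_pseudo_absences(presence_cells: np.ndarray,
                           grid: LandscapeGrid,
                           buffer_radius: float,
                           n_repetitions: int = DEFAULT_N_REPETITIONS,
                           seed: int = 0,
                           species_id: str = "?") -> list[TrainingSet]:
    """Draw pseudo-absence cells outside a buffer around all presences.

    Eligible cells are those whose centre lies strictly farther than
    ``buffer_radius`` (same length units as the grid) from every presence
    cell centre. Each repetition draws, without replacement and uniformly,
    exactly as many pseudo-absences as there are presences, so the
    training prevalence is exactly 0.5. Repetitions use independent
    substreams of ``seed``.
    """
    if buffer_radius < 0:
        raise ValueError("buffer radius must be >= 0")
    presence_cells = np.asarray(presence_cells, dtype=int)
    if presence_cells.size == 0:
        raise SpeciesSkipped(f"species {species_id}: no presences")
    centres = grid.cell_centres()
    pres = centres[presence_cells]
    # min distance of every cell centre to any presence centre
    d2 = ((centres[:, None, :] - pres[None, :, :]) ** 2).sum(axis=2)
    min_dist = np.sqrt(d2.min(axis=1))
    eligible = np.flatnonzero(min_dist > buffer_radius)
    n_pres = presence_cells.size
    if eligible.size < n_pres:
        raise ValueError(
            f"species {species_id}: only {eligible.size} cells lie outside "
            f"the {buffer_radius}-unit buffer but {n_pres} pseudo-absences "
            "are needed; consider a smaller buffer")
    streams = np.random.SeedSequence(seed).spawn(n_repetitions)
    sets = []
    for rep, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        pa_cells = rng.choice(eligible, size=n_pres, replace=False)
        cells = np.concatenate([presence_cells, pa_cells])
        labels = np.concatenate([np.ones(n_pres, dtype=np.int8),
                                 np.zeros(n_pres, dtype=np.int8)])
        sets.append(TrainingSet(species_id=species_id, repetition=rep,
                                cell_ids=cells, labels=labels))
    return sets


def real_absence_training_sets(presence_cells: np.ndarray,
                               absence_cells: np.ndarray,
                               n_repetitions: int = DEFAULT_N_REPETITIONS,
                               species_id: str = "?") -> list[TrainingSet]:
    """Training sets from recorded absences (tree-type species).

    The data are fixed; repetitions differ only through the downstream
    calibration/evaluation split.
    """
    presence_cells = np.asarray(presence_cells, dtype=int)
    absence_cells = np.asarray(absence_cells, dtype=int)
    if presence_cells.size == 0 or absence_cells.size == 0:
        raise SpeciesSkipped(
            f"species {species_id}: single-class occurrence data")
    cells = np.concatenate([presence_cells, absence_cells])
    labels = np.concatenate([
        np.ones(presence_cells.size, dtype=np.int8),
        np.zeros(absence_cells.size, dtype=np.int8)])
    return [TrainingSet(species_id=species_id, repetition=rep,
                        cell_ids=cells, labels=labels)
            for rep in range(1, n_repetitions + 1)]


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------

def build_features(climate: ClimateScenario, period: str,
                   predictor_set: PredictorSet,
                   soil: pd.DataFrame | None = None) -> np.ndarray:
    """Numeric design matrix over all cells for one period.

    Continuous climate predictors in the retained order; categorical soil
    covariates (trees) appended as fixed-width one-hot blocks so reference
    and future matrices always align column-for-column.
    """
    blocks = [np.column_stack([climate.values(v, period)
                               for v in predictor_set.retained])]
    if predictor_set.categorical:
        if soil is None:
            raise ValueError("predictor set needs soil layers but none given")
        widths = {"deposit": N_DEPOSIT_CLASSES,
                  "drainage": N_DRAINAGE_CLASSES}
        for col in predictor_set.categorical:
            vals = soil.sort_values("cell_id")[col].to_numpy()
            onehot = np.zeros((vals.size, widths[col]))
            onehot[np.arange(vals.size), vals] = 1.0
            blocks.append(onehot)
    return np.hstack(blocks)


# ---------------------------------------------------------------------------
# members, AUC, consensus
# ---------------------------------------------------------------------------

@dataclass
class MemberModel:
    family: str
    repetition: int
    estimator: object
    auc: float = float("nan")

    def predict_suitability(self, X: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(X)
        classes = list(self.estimator.classes_)
        if 1 not in classes:  # degenerate fit on one class
            return np.zeros(X.shape[0])
        return proba[:, classes.index(1)]


def fit_members(X: np.ndarray, y: np.ndarray,
                families: tuple[str, ...] = DEFAULT_FAMILIES,
                repetition: int = 1, seed: int = 0) -> list[MemberModel]:
    """Fit one member per family on a training design matrix."""
    if len(families) < 1:
        raise ValueError("need at least one model family")
    if np.unique(y).size < 2:
        raise SpeciesSkipped("single-class training set")
    members = []
    for i, fam in enumerate(families):
        factory = MODEL_FAMILIES.get(fam)
        if factory is None:
            raise ValueError(f"unknown model family {fam!r}")
        est = factory(fam, seed + i)
        if fam == "knn":
            k = int(np.clip(np.sqrt(y.size), 3, 25))
            est.set_params(clf__n_neighbors=min(k, y.size - 1))
        est.fit(X, y)
        members.append(MemberModel(family=fam, repetition=repetition,
                                   estimator=est))
    return members


def evaluate_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formulation; ties count one half.

    Equals the probability that a random presence outranks a random
    absence. Raises on a single-class holdout.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: holdout contains a single class")
    ranks = rankdata(scores)  # midranks for ties
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


def consensus_project(members: list[MemberModel], X: np.ndarray,
                      auc_floor: float = DEFAULT_AUC_FLOOR) -> np.ndarray:
    """AUC-weighted mean suitability over members at or above the floor."""
    kept = [m for m in members if m.auc >= auc_floor]
    if not kept:
        raise SpeciesSkipped(
            f"no ensemble member reached the AUC floor {auc_floor}")
    weights = np.array([m.auc for m in kept], dtype=float)
    weights /= weights.sum()
    preds = np.column_stack([m.predict_suitability(X) for m in kept])
    return preds @ weights


def max_tss_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Smallest score threshold maximizing TSS = sens + spec - 1.

    Candidate thresholds are the unique observed scores; presence is
    predicted where ``score >= threshold``.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("TSS threshold needs both classes")
    candidates = np.unique(scores)
    n1 = (labels == 1).sum()
    n0 = (labels == 0).sum()
    # vectorized: for each candidate t, sens = P(score>=t | y=1) etc.
    pred = scores[None, :] >= candidates[:, None]
    sens = (pred & (labels == 1)).sum(axis=1) / n1
    spec = (~pred & (labels == 0)).sum(axis=1) / n0
    tss = sens + spec - 1.0
    best = tss.max()
    return float(candidates[np.flatnonzero(tss >= best - 1e-12)[0]])


@dataclass
class SuitabilityMap:
    species_id: str
    period: str
    suitability: np.ndarray
    threshold: float

    @property
    def presence(self) -> np.ndarray:
        return (self.suitability >= self.threshold).astype(np.int8)


@dataclass
class SpeciesModelResult:
    species_id: str
    taxon: str
    status: str                      # "modelled" | "skipped"
    reason: str = ""
    members: list[MemberModel] = field(default_factory=list)
    threshold: float = float("nan")
    maps: dict[str, SuitabilityMap] = field(default_factory=dict)

    def member_report(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"species_id": self.species_id, "family": m.family,
              "repetition": m.repetition, "auc": m.auc}
             for m in self.members])


def _stratified_split(labels: np.ndarray, calibration_fraction: float,
                      rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Random calibration/evaluation split, stratified by class.

    Both sides keep at least one row of each class so training is
    two-class and the holdout AUC is defined.
    """
    cal_idx, eval_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise SpeciesSkipped(
                f"class {cls} has {idx.size} rows; cannot split")
        idx = rng.permutation(idx)
        n_cal = max(1, min(idx.size - 1,
                           int(round(calibration_fraction * idx.size))))
        cal_idx.append(idx[:n_cal])
        eval_idx.append(idx[n_cal:])
    return np.concatenate(cal_idx), np.concatenate(eval_idx)


def model_species(species_id: str,
                  taxon: str,
                  presence: np.ndarray,          # 0/1 over all cells
                  grid: LandscapeGrid,
                  climate: ClimateScenario,
                  predictor_set: PredictorSet,
                  soil: pd.DataFrame | None = None,
                  families: tuple[str, ...] = DEFAULT_FAMILIES,
                  n_repetitions: int = DEFAULT_N_REPETITIONS,
                  buffer_cells: float = DEFAULT_BUFFER_CELLS,
                  auc_floor: float = DEFAULT_AUC_FLOOR,
                  calibration_fraction: float = DEFAULT_CALIBRATION_FRACTION,
                  min_presences: int = 10,
                  seed: int = 0) -> SpeciesModelResult:
    """Full per-species workflow: train, evaluate, project, binarize.

    Non-tree taxa use pseudo-absences (buffer ``buffer_cells`` cell widths,
    prevalence 0.5, R repetitions); trees use their recorded absences.
    Members with holdout AUC below ``auc_floor`` are excluded from the
    consensus. The binarization threshold maximizes TSS of the
    reference-period consensus against the recorded occurrence labels over
    all cells and is applied identically to both periods.
    """
    presence = np.asarray(presence).astype(np.int8)
    presence_cells = np.flatnonzero(presence == 1)
    result = SpeciesModelResult(species_id=species_id, taxon=taxon,
                                status="modelled")
    try:
        if presence_cells.size == 0:
            raise SpeciesSkipped("no presences recorded")
        if presence_cells.size < min_presences:
            raise SpeciesSkipped(
                f"only {presence_cells.size} presences "
                f"(minimum {min_presences})")
        if presence_cells.size == grid.n_cells:
            raise SpeciesSkipped("present in every cell (no absences)")
        if taxon == "tree":
            training = real_absence_training_sets(
                presence_cells, np.flatnonzero(presence == 0),
                n_repetitions=n_repetitions, species_id=species_id)
        else:
            # widespread species can exhaust the eligible background at the
            # configured buffer; shrink it (keeping prevalence 0.5 exact)
            # rather than dropping the species
            buffer_radius = buffer_cells * grid.cell_size
            while True:
                try:
                    training = select_pseudo_absences(
                        presence_cells, grid, buffer_radius=buffer_radius,
                        n_repetitions=n_repetitions, seed=seed,
                        species_id=species_id)
                    break
                except ValueError:
                    if buffer_radius == 0:
                        raise SpeciesSkipped(
                            "more presences than available background cells")
                    buffer_radius = (buffer_radius / 2
                                     if buffer_radius > grid.cell_size / 4
                                     else 0.0)
                    log.warning(
                        "species %s: pseudo-absence buffer shrunk to %.2f "
                        "(too few eligible cells)", species_id,
                        buffer_radius)

        X_ref = build_features(climate, REFERENCE, predictor_set, soil=soil)
        X_fut = build_features(climate, FUTURE, predictor_set, soil=soil)

        split_streams = np.random.SeedSequence((seed, 1)).spawn(len(training))
        fit_seed = np.random.SeedSequence((seed, 2)).generate_state(1)[0]
        members: list[MemberModel] = []
        for ts, ss in zip(training, split_streams):
            rng = np.random.default_rng(ss)
            cal, hold = _stratified_split(ts.labels, calibration_fraction,
                                          rng)
            Xt = X_ref[ts.cell_ids]
            fitted = fit_members(Xt[cal], ts.labels[cal], families=families,
                                 repetition=ts.repetition,
                                 seed=int(fit_seed) + ts.repetition)
            for m in fitted:
                m.auc = evaluate_auc(m.predict_suitability(Xt[hold]),
                                     ts.labels[hold])
            members.extend(fitted)
        result.members = members

        excluded = [m for m in members if m.auc < auc_floor]
        if excluded:
            log.info("species %s: %d/%d members below AUC floor %.2f "
                     "excluded from consensus", species_id, len(excluded),
                     len(members), auc_floor)

        suit_ref = consensus_project(members, X_ref, auc_floor=auc_floor)
        suit_fut = consensus_project(members, X_fut, auc_floor=auc_floor)

        # Binary threshold: max TSS of the reference consensus against the
        # recorded occurrence labels over all cells (presence-vs-background
        # for pseudo-absence taxa, presence-vs-absence for trees). The
        # buffered training rows are deliberately depleted of absences near
        # range edges, so calibrating on them would bias the threshold low.
        thr = max_tss_threshold(suit_ref, presence)
        result.threshold = thr
        result.maps = {
            REFERENCE: SuitabilityMap(species_id, REFERENCE, suit_ref, thr),
            FUTURE: SuitabilityMap(species_id, FUTURE, suit_fut, thr),
        }
    except SpeciesSkipped as exc:
        log.warning("species %s skipped: %s", species_id, exc)
        result.status = "skipped"
        result.reason = str(exc)
    return result


def maps_to_long(results: list[SpeciesModelResult]) -> pd.DataFrame:
    """Long-format table of per-cell suitability and binary presence."""
    rows = []
    for res in results:
        if res.status != "modelled":
            continue
        for period in PERIODS:
            m = res.maps[period]
            rows.append(pd.DataFrame({
                "cell_id": np.arange(m.suitability.size),
                "species_id": res.species_id,
                "period": period,
                "suitability": m.suitability,
                "presence": m.presence}))
    if not rows:
        return pd.DataFrame(columns=["cell_id", "species_id", "period",
                                     "suitability", "presence"])
    return pd.concat(rows, ignore_index=True)


def presence_matrices(results: list[SpeciesModelResult], n_cells: int
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(reference, future) binary presence matrices, species x cells."""
    ref_rows, fut_rows, ids = [], [], []
    for res in results:
        if res.status != "modelled":
            continue
        ids.append(res.species_id)
        ref_rows.append(res.maps[REFERENCE].presence)
        fut_rows.append(res.maps[FUTURE].presence)
    ref = pd.DataFrame(np.vstack(ref_rows) if ref_rows
                       else np.empty((0, n_cells), dtype=np.int8), index=ids)
    fut = pd.DataFrame(np.vstack(fut_rows) if fut_rows
                       else np.empty((0, n_cells), dtype=np.int8), index=ids)
    return ref, fut
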