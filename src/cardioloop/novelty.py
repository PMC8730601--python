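"""Emerging-stress-state detection, latent embedding and type identification.

High-dose infusions (H-D, H-NE, H-D+NE; 5x the standard dose analogue)
present feature profiles the decoder was never trained on.  This module
detects such emerging states with an LSTM autoencoder (input 2730 = 210
steps x 13 features, hidden 256) trained only on known-state windows: a
window is flagged "unknown" when its mean squared reconstruction error
exceeds the 99th percentile of the training-loss distribution.  Two
comparators are included -- a sparse dense autoencoder (546 = 42 x 13 ->
50 -> 546) and an isolation forest (2 estimators, 140 max features, 0.16
outlier proportion).

The LSTM-AE's 256-d hidden layer is embedded to 2-D with supervised UMAP
(n_neighbors 15, min_dist 0.1), using the AE's own known/unknown prediction
as the supervision label; a linear SVM scores how well known and emerging
windows separate in that plane, and HDBSCAN clusters the emerging points so
a V-measure against the true high-dose type quantifies fully unsupervised
identification across the seven presentation scenarios.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .decode import LabeledSequenceSet
from .nn import LSTMAutoencoder, SparseAutoencoder

__all__ = [
    "SCENARIOS", "NoveltyConfig", "WindowMatrix", "NoveltyResult",
    "build_windows", "fit_autoencoder", "fit_isolation_forest",
    "score_novelty", "embed_latent", "boundary_separation",
    "identify_types", "v_measure", "run_novelty_suite",
]

EMERGING_TYPES = ("H-D", "H-NE", "H-D+NE")
# the seven presentation scenarios: every non-empty subset of the types
SCENARIOS = tuple(
    tuple(c) for r in (1, 2, 3) for c in itertools.combinations(EMERGING_TYPES, r))


@dataclass
class NoveltyConfig:
    """Detector, windowing and embedding settings."""

    # LSTM-AE: 210 steps x 13 features = 2730-unit encoder input
    lstm_steps: int = 210
    lstm_hidden: int = 256
    lstm_l2: float = 0.0
    lstm_epochs: int = 3
    lstm_batch: int = 32      # small batches: more Adam updates per epoch,
                              # which is what shapes the code geometry
    lstm_lr: float = 0.003
    # Sparse-AE: 42 x 13 = 546-unit input
    sparse_steps: int = 42
    sparse_hidden: int = 50
    sparse_l2: float = 0.1
    sparse_sparsity: float = 1.0
    sparse_epochs: int = 30
    # Iso-Forest
    iso_estimators: int = 2
    iso_max_features: int = 140
    iso_outlier_proportion: float = 0.16
    # windowing (steps of 100 ms).  Scoring windows are non-overlapping
    # observations (stride = window length) so the embedding's neighbor
    # graph spans recordings instead of saturating within one; training
    # windows overlap for sample efficiency.
    train_stride: int = 30
    score_stride: int = 210
    emerging_start: float = 124.0     # s; windows fully inside the settled
                                      # high-dose effect period count as
                                      # emerging-state observations
    # thresholding / embedding
    threshold_percentile: float = 99.0
    umap_neighbors: int = 15
    umap_min_dist: float = 0.1
    umap_components: int = 2
    # HDBSCAN minimum cluster size as a fraction of the expected per-type
    # window count (a type's windows form one cluster at scenario level)
    hdbscan_min_cluster_frac: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.lstm_hidden >= self.lstm_steps * 13:
            raise ValueError("LSTM-AE hidden layer must be smaller than its input")
        if self.sparse_hidden >= self.sparse_steps * 13:
            raise ValueError("Sparse-AE hidden layer must be smaller than its input")
        if not (0.0 < self.iso_outlier_proportion < 1.0):
            raise ValueError("outlier proportion must lie in (0, 1)")


@dataclass
class WindowMatrix:
    """Flattened feature windows with data-lineage tags."""

    X: np.ndarray            # (n, n_steps * 13)
    n_steps: int
    n_features: int
    source: np.ndarray       # state name per window
    record_index: np.ndarray
    lineage: np.ndarray      # "known" | "emerging" per window
    start_time: np.ndarray | None = None   # s, window start in the recording

    def __post_init__(self):
        if self.X.shape[1] != self.n_steps * self.n_features:
            raise ValueError("window width x features must equal the flat size exactly")
        if self.start_time is None:
            self.start_time = np.full(self.X.shape[0], np.nan)

    def __len__(self):
        return self.X.shape[0]

    def subset(self, mask) -> "WindowMatrix":
        mask = np.asarray(mask)
        return WindowMatrix(self.X[mask], self.n_steps, self.n_features,
                            self.source[mask], self.record_index[mask],
                            self.lineage[mask], self.start_time[mask])


@dataclass
class NoveltyResult:
    """Per-window scoring results of one detector."""

    loss: np.ndarray
    flagged: np.ndarray
    threshold: float
    sensitivity: float       # flag rate on emerging windows
    specificity: float       # 1 - flag rate on known windows
    latent: np.ndarray | None = None    # (n, 2) UMAP coordinates
    clusters: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def build_windows(dataset: LabeledSequenceSet, n_steps: int, stride: int,
                  lineage: str = "known", start_time: float | None = None,
                  step_period: float = 0.1, t0: float = 4.0) -> WindowMatrix:
    """Cut standardized recordings into flattened windows.

    Windows never span a recording boundary.  ``start_time`` (seconds from
    recording start) restricts windows to begin at or after that time --
    used to draw emerging windows from the settled high-dose effect period.
    """
    X, src, rid, lin, t_start = [], [], [], [], []
    start_idx = 0 if start_time is None else max(
        0, int(round((start_time - t0) / step_period)))
    for r, seq in enumerate(dataset.sequences):
        T = seq.shape[0]
        for s in range(start_idx, T - n_steps + 1, stride):
            X.append(seq[s:s + n_steps].ravel())
            src.append(dataset.record_states[r])
            rid.append(r)
            lin.append(lineage)
            t_start.append(t0 + s * step_period)
    if not X:
        return WindowMatrix(np.empty((0, n_steps * dataset.n_features)),
                            n_steps, dataset.n_features,
                            np.array([], dtype=object), np.array([], dtype=int),
                            np.array([], dtype=object), np.array([]))
    return WindowMatrix(np.asarray(X, dtype=np.float32), n_steps,
                        dataset.n_features, np.array(src, dtype=object),
                        np.array(rid, dtype=int), np.array(lin, dtype=object),
                        np.array(t_start))


def _assert_known(windows: WindowMatrix):
    if (windows.lineage != "known").any():
        raise ValueError("training windows must all carry 'known' lineage "
                         "(the detector may never see emerging states in training)")


def fit_autoencoder(windows: WindowMatrix, config: NoveltyConfig | None = None,
                    kind: str = "lstm", seed: int | None = None):
    """Train an autoencoder on known-state windows only.

    Returns the fitted model; its ``train_losses_`` attribute holds the
    training reconstruction-loss distribution used for threshold setting,
    and ``hidden`` exposes the latent code accessor.
    """
    config = config or NoveltyConfig()
    _assert_known(windows)
    seed = config.seed if seed is None else seed
    if kind == "lstm":
        model = LSTMAutoencoder(
            n_steps=config.lstm_steps, n_features=windows.n_features,
            hidden_units=config.lstm_hidden, l2=config.lstm_l2,
            epochs=config.lstm_epochs, batch_size=config.lstm_batch,
            lr=config.lstm_lr, seed=seed)
    elif kind == "sparse":
        model = SparseAutoencoder(
            n_inputs=config.sparse_steps * windows.n_features,
            hidden_units=config.sparse_hidden, l2=config.sparse_l2,
            sparsity_target=config.sparse_sparsity,
            epochs=config.sparse_epochs, seed=seed)
    else:
        raise ValueError(f"unknown autoencoder kind {kind!r}")
    if windows.X.shape[1] != model.input_size:
        raise ValueError(
            f"window width {windows.X.shape[1]} != encoder input {model.input_size}")
    model.fit(windows.X)
    return model


def fit_isolation_forest(windows: WindowMatrix, config: NoveltyConfig | None = None,
                         seed: int | None = None):
    """Isolation-forest comparator on the (sparse-dialect) windows."""
    from sklearn.ensemble import IsolationForest

    config = config or NoveltyConfig()
    _assert_known(windows)
    est = IsolationForest(
        n_estimators=config.iso_estimators,
        max_features=min(config.iso_max_features, windows.X.shape[1]),
        contamination=config.iso_outlier_proportion,
        random_state=config.seed if seed is None else seed)
    est.fit(windows.X)
    return est


def novelty_threshold(train_losses: np.ndarray, percentile: float = 99.0) -> float:
    return float(np.percentile(np.asarray(train_losses), percentile))


def score_novelty(model, windows: WindowMatrix, threshold: float | None = None,
                  config: NoveltyConfig | None = None) -> NoveltyResult:
    """Flag windows whose reconstruction loss exceeds the threshold.

    ``threshold`` defaults to the configured percentile of the model's
    training-loss distribution.  Sensitivity is the flag rate on windows
    with 'emerging' lineage, specificity the pass rate on 'known' windows.
    """
    config = config or NoveltyConfig()
    if getattr(model, "train_losses_", None) is None:
        raise ValueError("model has not been fitted")
    if threshold is None:
        threshold = novelty_threshold(model.train_losses_, config.threshold_percentile)
    loss = model.loss(windows.X)
    flagged = loss > threshold
    emerging = windows.lineage == "emerging"
    known = ~emerging
    sens = float(np.mean(flagged[emerging])) if emerging.any() else np.nan
    spec = float(np.mean(~flagged[known])) if known.any() else np.nan
    return NoveltyResult(loss=loss, flagged=flagged, threshold=float(threshold),
                         sensitivity=sens, specificity=spec)


def score_isolation_forest(est, windows: WindowMatrix) -> NoveltyResult:
    pred = est.predict(windows.X)          # -1 = outlier
    flagged = pred == -1
    emerging = windows.lineage == "emerging"
    known = ~emerging
    sens = float(np.mean(flagged[emerging])) if emerging.any() else np.nan
    spec = float(np.mean(~flagged[known])) if known.any() else np.nan
    return NoveltyResult(loss=-est.score_samples(windows.X), flagged=flagged,
                         threshold=np.nan, sensitivity=sens, specificity=spec)


# ---------------------------------------------------------------------------
# latent space
# ---------------------------------------------------------------------------

def embed_latent(hidden: np.ndarray, labels, n_neighbors: int = 15,
                 min_dist: float = 0.1, n_components: int = 2,
                 seed: int = 0) -> np.ndarray:
    """Supervised UMAP of the autoencoder hidden vectors to 2-D.

    ``labels`` are the supervision target (the AE's known/unknown
    prediction per window).  Deterministic under a fixed seed.
    """
    import umap

    hidden = np.asarray(hidden, dtype=np.float32)
    if hidden.shape[0] < n_neighbors + 1:
        raise ValueError(f"need at least {n_neighbors + 1} windows, got {hidden.shape[0]}")
    labels = np.asarray(labels)
    y = np.unique(labels, return_inverse=True)[1]
    reducer = umap.UMAP(n_neighbors=n_neighbors, min_dist=min_dist,
                        n_components=n_components, random_state=seed)
    return np.asarray(reducer.fit_transform(hidden, y=y), dtype=float)


def boundary_separation(points: np.ndarray, truth: np.ndarray, seed: int = 0,
                        n_permutations: int = 10):
    """Accuracy of the best linear boundary between the two classes.

    Fits a linear max-margin SVM on the 2-D points and scores it on the
    same points; the chance level is the same fit/score under label
    permutation.  Returns (accuracy, chance dict).
    """
    from sklearn.svm import SVC

    points = np.asarray(points, dtype=float)
    truth = np.asarray(truth)
    classes = np.unique(truth)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    svm = SVC(kernel="linear", C=1.0)
    svm.fit(points, truth)
    acc = float(svm.score(points, truth))
    rng = np.random.default_rng(seed)
    perm = []
    for _ in range(n_permutations):
        yp = rng.permutation(truth)
        if np.unique(yp).size < 2:
            continue
        s = SVC(kernel="linear", C=1.0)
        s.fit(points, yp)
        perm.append(float(s.score(points, yp)))
    chance = {"mean": float(np.mean(perm)) if perm else np.nan,
              "sd": float(np.std(perm)) if perm else np.nan,
              "values": perm}
    return acc, chance


def v_measure(truth, clusters):
    """Homogeneity, completeness and V-measure from label entropies.

    All three lie in [0, 1]; a labeling with zero entropy on either side is
    perfectly homogeneous (resp. complete) by convention, matching the
    standard definition.  Invariant to cluster-id permutation.
    """
    truth = np.asarray(truth)
    clusters = np.asarray(clusters)
    if truth.size == 0 or truth.shape != clusters.shape:
        raise ValueError("label vectors must be equal-length and non-empty")
    n = truth.size
    _, ti = np.unique(truth, return_inverse=True)
    _, ci = np.unique(clusters, return_inverse=True)
    nt, nc = ti.max() + 1, ci.max() + 1
    cont = np.zeros((nt, nc))
    np.add.at(cont, (ti, ci), 1.0)

    def _ent(p):
        p = p[p > 0] / n
        return float(-np.sum(p * np.log(p)))

    h_c = _ent(cont.sum(axis=1))
    h_k = _ent(cont.sum(axis=0))
    # conditional entropies from the contingency table
    pj = cont.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_c_given_k = -np.nansum(
            np.where(cont > 0, (cont / n) * np.log(cont / np.maximum(pj, 1e-300)), 0.0))
    pi = cont.sum(axis=1)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        h_k_given_c = -np.nansum(
            np.where(cont > 0, (cont / n) * np.log(cont / np.maximum(pi, 1e-300)), 0.0))
    hom = 1.0 if h_c == 0.0 else 1.0 - h_c_given_k / h_c
    com = 1.0 if h_k == 0.0 else 1.0 - h_k_given_c / h_k
    v = 0.0 if hom + com == 0.0 else 2.0 * hom * com / (hom + com)
    return float(hom), float(com), float(v)


def _assign_noise_points(points, labels):
    """Give HDBSCAN noise points the label of the nearest clustered point;
    V-measure needs a complete labeling of the scenario windows."""
    if (labels >= 0).any() and (labels < 0).any():
        from scipy.spatial import cKDTree

        labels = labels.copy()
        tree = cKDTree(points[labels >= 0])
        _, idx = tree.query(points[labels < 0])
        labels[labels < 0] = labels[labels >= 0][idx]
    return labels


def identify_types(points: np.ndarray, types: np.ndarray,
                   scenarios=SCENARIOS, config: NoveltyConfig | None = None,
                   allow_missing: bool = False):
    """Unsupervised identification of emerging-state types with HDBSCAN.

    For each presentation scenario (a subset of the high-dose types), the
    2-D latent points of that scenario's windows are clustered; homogeneity,
    completeness and V-measure are computed against the true type labels.
    The minimum cluster size scales with the expected per-type window count
    and low-density (noise) points inherit the nearest cluster, so the
    granularity matches the type level for one- and multi-type scenarios
    alike.  Returns per-scenario rows and the mean performance
    (V-measure x 100).
    """
    from sklearn.cluster import HDBSCAN

    config = config or NoveltyConfig()
    points = np.asarray(points, dtype=float)
    types = np.asarray(types, dtype=object)
    per_type = {t: int(np.sum(types == t)) for t in np.unique(types)}
    rows = []
    for scenario in scenarios:
        mask = np.isin(types, list(scenario))
        if not mask.any():
            if allow_missing:
                # nothing of this scenario was flagged: identification failed
                rows.append({"scenario": "+".join(scenario), "n_windows": 0,
                             "n_clusters": 0, "noise_fraction": np.nan,
                             "homogeneity": np.nan, "completeness": np.nan,
                             "v_measure": 0.0, "performance": 0.0})
                continue
            raise ValueError(f"scenario {scenario} has no windows")
        pts, tt = points[mask], types[mask]
        w_type = float(np.mean([per_type.get(t, 0) for t in scenario]))
        mcs = max(3, int(round(config.hdbscan_min_cluster_frac * w_type)))
        mcs = min(mcs, max(2, pts.shape[0] - 1))
        raw = HDBSCAN(min_cluster_size=mcs).fit_predict(pts)
        labels = _assign_noise_points(pts, raw)
        hom, com, v = v_measure(tt, labels)
        rows.append({"scenario": "+".join(scenario), "n_windows": int(mask.sum()),
                     "n_clusters": int(np.unique(raw[raw >= 0]).size),
                     "noise_fraction": float(np.mean(raw < 0)),
                     "homogeneity": hom, "completeness": com,
                     "v_measure": v, "performance": 100.0 * v})
    mean_perf = float(np.mean([r["performance"] for r in rows]))
    return rows, mean_perf


# ---------------------------------------------------------------------------
# cross-validated suite
# ---------------------------------------------------------------------------

def _fold_split(n_records, test_fraction, rng):
    idx = rng.permutation(n_records)
    n_test = max(1, int(round(test_fraction * n_records)))
    return np.sort(idx[n_test:]), np.sort(idx[:n_test])


def run_novelty_suite(known: LabeledSequenceSet, emerging: LabeledSequenceSet,
                      config: NoveltyConfig | None = None, k: int = 10,
                      test_fraction: float = 0.2, seed: int = 0,
                      detectors=("lstm", "sparse", "iso")) -> dict:
    """The full emerging-state analysis, cross-validated by recording.

    Per fold: train each detector on windows from 80 % of the known-state
    recordings; flag held-out known windows (specificity) and high-dose
    windows (sensitivity); embed the LSTM-AE hidden vectors of all scored
    windows with supervised UMAP; score the linear known/unknown boundary;
    cluster the emerging windows per presentation scenario.  Emerging
    recordings are never part of any training set.
    """
    config = config or NoveltyConfig()
    rng = np.random.default_rng(seed)
    res: dict = {"folds": [], "config": config}
    lstm_train = build_windows(known, config.lstm_steps, config.train_stride)
    lstm_known_all = build_windows(known, config.lstm_steps, config.score_stride)
    # score the full high-dose recordings; the settled-effect subset defines
    # the emerging-state observations for the sensitivity metric
    lstm_emerging = build_windows(emerging, config.lstm_steps, config.score_stride,
                                  lineage="emerging")
    settled = lstm_emerging.start_time >= config.emerging_start - 1e-9
    sp_train = build_windows(known, config.sparse_steps, config.train_stride)
    sp_known_all = build_windows(known, config.sparse_steps, config.score_stride)
    sp_emerging = build_windows(emerging, config.sparse_steps, config.score_stride,
                                lineage="emerging", start_time=config.emerging_start)
    if not settled.any():
        raise ValueError("no emerging windows")

    for fold in range(k):
        tr, te = _fold_split(len(known), test_fraction, rng)
        fold_seed = seed + 1000 * fold
        row: dict = {"fold": fold}

        if "lstm" in detectors:
            ae = fit_autoencoder(lstm_train.subset(np.isin(lstm_train.record_index, tr)),
                                 config, kind="lstm", seed=fold_seed)
            test_known = lstm_known_all.subset(np.isin(lstm_known_all.record_index, te))
            sc_known = score_novelty(ae, test_known, config=config)
            sc_all = score_novelty(ae, lstm_emerging, config=config)
            row["lstm_sensitivity"] = float(np.mean(sc_all.flagged[settled]))
            row["lstm_specificity"] = sc_known.specificity
            row["n_emerging_windows"] = int(settled.sum())
            row["n_scored_windows"] = int(len(test_known) + len(lstm_emerging))
            # latent embedding of everything this fold scored
            hid = np.vstack([ae.hidden(test_known.X), ae.hidden(lstm_emerging.X)])
            pred_flags = np.concatenate([sc_known.flagged, sc_all.flagged])
            truth_lineage = np.concatenate([test_known.lineage, lstm_emerging.lineage])
            coords = embed_latent(hid, pred_flags,
                                  n_neighbors=config.umap_neighbors,
                                  min_dist=config.umap_min_dist,
                                  n_components=config.umap_components,
                                  seed=fold_seed)
            # boundary: known vs settled emerging (transition windows are
            # ambiguous by construction and excluded from the truth labels)
            bnd_mask = np.concatenate([np.ones(len(test_known), dtype=bool), settled])
            acc, chance = boundary_separation(coords[bnd_mask],
                                              truth_lineage[bnd_mask],
                                              seed=fold_seed)
            row["boundary_accuracy"] = acc
            row["boundary_chance"] = chance["mean"]
            # unsupervised typing of the windows the detector flagged
            emerg_mask = (truth_lineage == "emerging") & pred_flags
            emerg_pts = coords[emerg_mask]
            rows, mean_perf = identify_types(
                emerg_pts, lstm_emerging.source[sc_all.flagged], config=config,
                allow_missing=True)
            row["scenario_rows"] = rows
            row["scenario_mean_performance"] = mean_perf

        if "sparse" in detectors:
            sae = fit_autoencoder(sp_train.subset(np.isin(sp_train.record_index, tr)),
                                  config, kind="sparse", seed=fold_seed)
            s_known = score_novelty(
                sae, sp_known_all.subset(np.isin(sp_known_all.record_index, te)),
                config=config)
            s_emerg = score_novelty(sae, sp_emerging, config=config)
            row["sparse_sensitivity"] = s_emerg.sensitivity
            row["sparse_specificity"] = s_known.specificity

        if "iso" in detectors:
            iso = fit_isolation_forest(
                sp_train.subset(np.isin(sp_train.record_index, tr)), config,
                seed=fold_seed)
            i_known = score_isolation_forest(
                iso, sp_known_all.subset(np.isin(sp_known_all.record_index, te)))
            i_emerg = score_isolation_forest(iso, sp_emerging)
            row["iso_sensitivity"] = i_emerg.sensitivity
            row["iso_specificity"] = i_known.specificity

        res["folds"].append(row)

    for key in ("lstm_sensitivity", "sparse_sensitivity", "iso_sensitivity",
                "lstm_specificity", "boundary_accuracy",
                "scenario_mean_performance"):
        vals = [f[key] for f in res["folds"] if key in f]
        if vals:
            res[f"mean_{key}"] = float(np.mean(vals))
    return res
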