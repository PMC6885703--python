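"""One-hidden-layer binding-core network with two output neurons.

The network scores a (peptide, allele) pair by evaluating every candidate
binding core and taking the maximum of the requested output neuron
(output 0 = binding affinity, output 1 = eluted-ligand likelihood).
Training is per-example stochastic gradient descent on the squared error of
the single relevant output neuron, backpropagated through the argmax core
only.  Input->hidden and hidden-layer weights are shared between the two
outputs, so both data types shape the same internal representation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels
from .encoding import (
    AllelePseudoSequence,
    BindingCore,
    EncodingMatrix,
    FeatureLayout,
    blosum_encoding,
    encode_peptide_features,
    encode_pseudo,
    enumerate_cores,
)

OUTPUT_BA = 0
OUTPUT_EL = 1
OUTPUT_INDEX = {"BA": OUTPUT_BA, "EL": OUTPUT_EL}

_INIT_SCALE = 0.1


@dataclass
class TrainConfig:
    """Hyper-parameters of the training loop and its annotation schedule."""

    learning_rate: float = 0.05
    n_iterations: int = 200
    burn_in: int = 20
    hidden_sizes: tuple[int, ...] = (56, 66)
    seeds_per_size: int = 5
    n_partitions: int = 5
    early_stopping: bool = True
    core_len: int = 9
    length_bounds: tuple[int, int] = (8, 14)
    task: str = "classI"
    rescale: bool = True
    rescale_shift: float = 75.0
    rescale_scale: float = 10.0
    n_rescale_peptides: int = 10000
    motif_random_peptides: int = 200000
    motif_top_frac: float = 0.001

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn-in must be shorter than the training run")
        if not 50.0 <= self.rescale_shift <= 100.0:
            raise ValueError("rescale shift accepted in [50, 100]")

    def layout(self, pseudo_len: int) -> FeatureLayout:
        return FeatureLayout(core_len=self.core_len,
                             length_bounds=tuple(self.length_bounds),
                             pseudo_len=pseudo_len,
                             class2=self.task == "classII")


@dataclass
class NetworkModel:
    """Weights of one network.  ``wpt``/``wat`` are the transposed
    input->hidden blocks for the peptide-side and allele-side features."""

    wpt: np.ndarray          # (H, dim_peptide)
    wat: np.ndarray          # (H, dim_allele)
    bh: np.ndarray           # (H,)
    wo: np.ndarray           # (H, 2)
    bo: np.ndarray           # (2,)
    hidden_size: int
    seed_key: tuple[int, ...] = ()
    test_fold: int = -1

    def copy_weights(self) -> tuple[np.ndarray, ...]:
        return (self.wpt.copy(), self.wat.copy(), self.bh.copy(),
                self.wo.copy(), self.bo.copy())

    def set_weights(self, w: tuple[np.ndarray, ...]) -> None:
        self.wpt[...], self.wat[...], self.bh[...], self.wo[...], self.bo[...] = w


def init_network(layout: FeatureLayout, hidden_size: int,
                 seed_key: tuple[int, ...], test_fold: int = -1) -> NetworkModel:
    """Uniform(-0.1, 0.1) initialisation from a per-network seed key."""
    rng = np.random.default_rng(list(seed_key))
    def u(*shape):
        return rng.uniform(-_INIT_SCALE, _INIT_SCALE, size=shape)
    return NetworkModel(
        wpt=u(hidden_size, layout.dim_peptide),
        wat=u(hidden_size, layout.dim_allele),
        bh=u(hidden_size),
        wo=u(hidden_size, 2),
        bo=u(2),
        hidden_size=hidden_size,
        seed_key=tuple(seed_key),
        test_fold=test_fold,
    )


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Reference (numpy) forward and gradients
# ---------------------------------------------------------------------------

def forward(model: NetworkModel, peptide: str,
            pseudo: AllelePseudoSequence, layout: FeatureLayout,
            enc: EncodingMatrix, output: str = "EL",
            mode: str | None = None) -> tuple[float, BindingCore]:
    """Score a peptide against one allele: max over candidate cores of the
    requested output neuron.  Ties break to the lowest core index."""
    o = OUTPUT_INDEX[output]
    mode = mode or ("window" if layout.class2 else "indel")
    cores = enumerate_cores(peptide, layout.core_len, layout.length_bounds,
                            mode=mode)
    arow = encode_pseudo(pseudo, layout, enc)
    ph = model.wat @ arow + model.bh
    best, best_core = -np.inf, cores[0]
    for core in cores:
        x = encode_peptide_features(core, peptide, layout, enc)
        h = _sigmoid(model.wpt @ x + ph)
        out = float(_sigmoid(h @ model.wo[:, o] + model.bo[o]))
        if out > best:
            best, best_core = out, core
    return best, best_core


def core_output(model: NetworkModel, x_pep: np.ndarray, arow: np.ndarray,
                o: int) -> float:
    """Output of neuron ``o`` for one already-encoded core."""
    h = _sigmoid(model.wpt @ x_pep + model.wat @ arow + model.bh)
    return float(_sigmoid(h @ model.wo[:, o] + model.bo[o]))


def loss_gradients(model: NetworkModel, x_pep: np.ndarray, arow: np.ndarray,
                   target: float, o: int) -> dict[str, np.ndarray]:
    """Analytic gradients of 0.5*(out - target)^2 for one core.

    Reference implementation used by the gradient-correctness tests and the
    single-example update; the training kernel must match it exactly.
    """
    h = _sigmoid(model.wpt @ x_pep + model.wat @ arow + model.bh)
    out = float(_sigmoid(h @ model.wo[:, o] + model.bo[o]))
    go = (out - target) * out * (1.0 - out)
    gh = go * model.wo[:, o] * h * (1.0 - h)
    grads = {
        "wpt": np.outer(gh, x_pep),
        "wat": np.outer(gh, arow),
        "bh": gh,
        "wo": np.zeros_like(model.wo),
        "bo": np.zeros_like(model.bo),
    }
    grads["wo"][:, o] = go * h
    grads["bo"][o] = go
    return grads


def sgd_update(model: NetworkModel, peptide: str,
               pseudo: AllelePseudoSequence, target: float, assay: str,
               layout: FeatureLayout, enc: EncodingMatrix, lr: float,
               mode: str | None = None) -> BindingCore:
    """In-place per-example update through the argmax core.

    Only the requested output neuron's private weights move; the shared
    input->hidden block is updated for both assay types.
    """
    o = OUTPUT_INDEX[assay]
    score, core = forward(model, peptide, pseudo, layout, enc, output=assay,
                          mode=mode)
    x = encode_peptide_features(core, peptide, layout, enc)
    arow = encode_pseudo(pseudo, layout, enc)
    grads = loss_gradients(model, x, arow, target, o)
    model.wpt -= lr * grads["wpt"]
    model.wat -= lr * grads["wat"]
    model.bh -= lr * grads["bh"]
    model.wo -= lr * grads["wo"]
    model.bo -= lr * grads["bo"]
    return core


# ---------------------------------------------------------------------------
# Pre-encoded training arrays
# ---------------------------------------------------------------------------

@dataclass
class TrainingArrays:
    """All records of a run, encoded once.

    ``allele_idx`` points into ``allele_enc``; MA records hold -1 until they
    are annotated.  Candidate cores of record ``i`` occupy rows
    ``core_start[i] : core_start[i] + core_count[i]`` of ``core_feats``.
    """

    core_feats: np.ndarray   # (n_cores_total, dim_peptide)
    core_start: np.ndarray   # (n,) int64
    core_count: np.ndarray   # (n,) int64
    allele_idx: np.ndarray   # (n,) int64, -1 = unassigned
    target: np.ndarray       # (n,) float
    out_idx: np.ndarray      # (n,) int64
    partition: np.ndarray    # (n,) int64
    is_ma: np.ndarray        # (n,) bool
    is_positive: np.ndarray  # (n,) bool
    labels: np.ndarray       # (n,) object
    peptides: np.ndarray     # (n,) object
    allele_names: list[str]
    allele_enc: np.ndarray   # (n_alleles, dim_allele)
    layout: FeatureLayout
    cores: list[str]         # core string per core_feats row

    @property
    def n_records(self) -> int:
        return len(self.target)

    def allele_index(self, name: str) -> int:
        return self.allele_names.index(name)


def build_training_arrays(records, pseudo_table: dict[str, AllelePseudoSequence],
                          layout: FeatureLayout,
                          enc: EncodingMatrix | None = None,
                          allele_names: list[str] | None = None) -> TrainingArrays:
    """Encode a record DataFrame (see :mod:`madeconv.data`) into flat arrays.

    Record order is preserved; callers are responsible for a deterministic
    ordering of the input frame.
    """
    enc = enc or blosum_encoding()
    if allele_names is None:
        allele_names = sorted(pseudo_table)
    allele_pos = {a: i for i, a in enumerate(allele_names)}
    allele_enc = np.stack([
        encode_pseudo(pseudo_table[a], layout, enc) for a in allele_names])

    mode = "window" if layout.class2 else "indel"
    feats: list[np.ndarray] = []
    core_strs: list[str] = []
    starts = np.zeros(len(records), dtype=np.int64)
    counts = np.zeros(len(records), dtype=np.int64)
    pep_cache: dict[str, tuple[int, int]] = {}
    pos = 0
    peptides = records["peptide"].to_numpy()
    for i, pep in enumerate(peptides):
        cached = pep_cache.get(pep)
        if cached is not None:
            starts[i], counts[i] = cached
            continue
        cores = enumerate_cores(pep, layout.core_len, layout.length_bounds,
                                mode=mode)
        for core in cores:
            feats.append(encode_peptide_features(core, pep, layout, enc))
            core_strs.append(core.core)
        starts[i], counts[i] = pos, len(cores)
        pep_cache[pep] = (pos, len(cores))
        pos += len(cores)

    origin = records["origin"].to_numpy()
    is_ma = origin == "MA"
    allele_idx = np.full(len(records), -1, dtype=np.int64)
    for i, (ma, label) in enumerate(zip(is_ma, records["label"].to_numpy())):
        if not ma:
            allele_idx[i] = allele_pos[label]

    return TrainingArrays(
        core_feats=np.ascontiguousarray(np.stack(feats)) if feats else
        np.zeros((0, layout.dim_peptide)),
        core_start=starts,
        core_count=counts,
        allele_idx=allele_idx,
        target=records["target"].to_numpy(dtype=float),
        out_idx=np.where(records["assay"].to_numpy() == "BA",
                         OUTPUT_BA, OUTPUT_EL).astype(np.int64),
        partition=records["partition"].to_numpy(dtype=np.int64),
        is_ma=is_ma,
        is_positive=records["target"].to_numpy(dtype=float) > 0,
        labels=records["label"].to_numpy(),
        peptides=peptides,
        allele_names=list(allele_names),
        allele_enc=allele_enc,
        layout=layout,
        cores=core_strs,
    )


def encode_ninemers(peptides: list[str], layout: FeatureLayout,
                    enc: EncodingMatrix) -> np.ndarray:
    """Vectorised peptide-side encoding for core-length peptides (one core)."""
    from .encoding import AA_INDEX, N_RESIDUES
    n = len(peptides)
    idx = np.array([[AA_INDEX[ch] for ch in p] for p in peptides])
    out = np.zeros((n, layout.dim_peptide))
    out[:, :layout.core_len * N_RESIDUES] = (
        enc.values[idx].reshape(n, -1))
    lo, _ = layout.length_bounds
    out[:, layout.core_len * N_RESIDUES + (layout.core_len - lo)] = 1.0
    return out


# ---------------------------------------------------------------------------
# Epoch driver and fold training
# ---------------------------------------------------------------------------

def epoch_order(seed_key: tuple[int, ...], epoch: int,
                active: np.ndarray) -> np.ndarray:
    """Deterministic shuffled example order for one epoch of one network."""
    rng = np.random.default_rng(list(seed_key) + [1000 + epoch])
    return active[rng.permutation(len(active))]


def run_epoch(model: NetworkModel, arrays: TrainingArrays,
              order: np.ndarray, lr: float) -> None:
    _kernels.sgd_epoch(model.wpt, model.wat, model.bh, model.wo, model.bo,
                       arrays.core_feats, arrays.core_start, arrays.core_count,
                       arrays.allele_idx, arrays.allele_enc, arrays.target,
                       arrays.out_idx, np.ascontiguousarray(order), lr)


def stop_set_error(model: NetworkModel, arrays: TrainingArrays,
                   indices: np.ndarray) -> float:
    return float(_kernels.batch_mse(
        model.wpt, model.wat, model.bh, model.wo, model.bo,
        arrays.core_feats, arrays.core_start, arrays.core_count,
        arrays.allele_idx, arrays.allele_enc, arrays.target, arrays.out_idx,
        np.ascontiguousarray(indices)))


def train_fold(arrays: TrainingArrays, train_idx: np.ndarray,
               stop_idx: np.ndarray, hidden_size: int, config: TrainConfig,
               seed_key: tuple[int, ...], test_fold: int = -1) -> NetworkModel:
    """Train one network on pre-encoded records with optional early stopping.

    ``train_idx``/``stop_idx`` must be disjoint by partition.  With early
    stopping the weight snapshot with the lowest stop-set mean squared error
    is retained.
    """
    if len(train_idx) == 0:
        raise ValueError("empty training set")
    model = init_network(arrays.layout, hidden_size, seed_key, test_fold)
    best_err = np.inf
    best_w = None
    for epoch in range(1, config.n_iterations + 1):
        order = epoch_order(seed_key, epoch, train_idx)
        run_epoch(model, arrays, order, config.learning_rate)
        if config.early_stopping and len(stop_idx):
            err = stop_set_error(model, arrays, stop_idx)
            if err < best_err:
                best_err = err
                best_w = model.copy_weights()
    if config.early_stopping and best_w is not None:
        model.set_weights(best_w)
    return model


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------

@dataclass
class Ensemble:
    """A collection of trained networks plus everything needed to predict."""

    members: list[NetworkModel]
    layout: FeatureLayout
    enc: EncodingMatrix
    pseudo_table: dict[str, AllelePseudoSequence]
    config: TrainConfig

    def __post_init__(self):
        if not self.members:
            raise ValueError("empty ensemble")

    def fold_members(self, fold: int) -> list[NetworkModel]:
        """Members whose held-out test fold is ``fold`` (out-of-fold for
        records living in that partition)."""
        members = [m for m in self.members if m.test_fold == fold]
        if not members:
            raise ValueError(f"no ensemble member for fold {fold}")
        return members

    def predict(self, peptide: str, allele: str, output: str = "EL",
                fold: int | None = None) -> float:
        """Arithmetic mean of member forward scores (max over cores each)."""
        members = self.members if fold is None else self.fold_members(fold)
        pseudo = self.pseudo_table[allele]
        return float(np.mean([
            forward(m, peptide, pseudo, self.layout, self.enc, output)[0]
            for m in members]))

    def predict_with_core(self, peptide: str, allele: str,
                          output: str = "EL",
                          fold: int | None = None) -> tuple[float, BindingCore]:
        """Ensemble score plus the argmax core of the mean per-core score."""
        members = self.members if fold is None else self.fold_members(fold)
        pseudo = self.pseudo_table[allele]
        mode = "window" if self.layout.class2 else "indel"
        cores = enumerate_cores(peptide, self.layout.core_len,
                                self.layout.length_bounds, mode=mode)
        arow = encode_pseudo(pseudo, self.layout, self.enc)
        o = OUTPUT_INDEX[output]
        per_core = np.zeros(len(cores))
        for m in members:
            ph = m.wat @ arow + m.bh
            for ci, core in enumerate(cores):
                x = encode_peptide_features(core, peptide, self.layout, self.enc)
                h = _sigmoid(m.wpt @ x + ph)
                per_core[ci] += _sigmoid(h @ m.wo[:, o] + m.bo[o])
        per_core /= len(members)
        ci = int(np.argmax(per_core))
        return float(per_core[ci]), cores[ci]

    def batch_predict(self, arrays: TrainingArrays, indices: np.ndarray,
                      allele: str, output: str = "EL",
                      members: list[NetworkModel] | None = None) -> np.ndarray:
        """Mean max-over-cores scores for pre-encoded records vs one allele."""
        members = members if members is not None else self.members
        o = OUTPUT_INDEX[output]
        arow = arrays.allele_enc[arrays.allele_index(allele)]
        starts = np.ascontiguousarray(arrays.core_start[indices])
        counts = np.ascontiguousarray(arrays.core_count[indices])
        total = np.zeros(len(indices))
        for m in members:
            scores, _ = _kernels.batch_scores(
                m.wpt, m.wat, m.bh, m.wo, m.bo,
                arrays.core_feats, starts, counts, arow, o)
            total += scores
        return total / len(members)


def ensemble_predict(ensemble: Ensemble, peptide: str, allele: str,
                     output: str = "EL") -> float:
    return ensemble.predict(peptide, allele, output)


# ---------------------------------------------------------------------------
# Serialization (versioned JSON container; round-trip exact)
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_ensemble(ensemble: Ensemble, path) -> None:
    doc = {
        "format_version": _FORMAT_VERSION,
        "config": {**asdict(ensemble.config),
                   "hidden_sizes": list(ensemble.config.hidden_sizes),
                   "length_bounds": list(ensemble.config.length_bounds)},
        "layout": {
            "core_len": ensemble.layout.core_len,
            "length_bounds": list(ensemble.layout.length_bounds),
            "pseudo_len": ensemble.layout.pseudo_len,
            "class2": ensemble.layout.class2,
        },
        "encoding": ensemble.enc.name,
        "pseudo_table": {a: p.residues
                         for a, p in ensemble.pseudo_table.items()},
        "members": [
            {
                "hidden_size": m.hidden_size,
                "seed_key": list(m.seed_key),
                "test_fold": m.test_fold,
                "wpt": m.wpt.tolist(),
                "wat": m.wat.tolist(),
                "bh": m.bh.tolist(),
                "wo": m.wo.tolist(),
                "bo": m.bo.tolist(),
            }
            for m in ensemble.members
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_ensemble(path) -> Ensemble:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {doc.get('format_version')}")
    cfg = doc["config"]
    cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
    cfg["length_bounds"] = tuple(cfg["length_bounds"])
    config = TrainConfig(**cfg)
    lay = doc["layout"]
    layout = FeatureLayout(core_len=lay["core_len"],
                           length_bounds=tuple(lay["length_bounds"]),
                           pseudo_len=lay["pseudo_len"],
                           class2=lay["class2"])
    name, _, scale = doc["encoding"].partition("/")
    enc = blosum_encoding(name.upper(), float(scale) if scale else 5.0)
    pseudo = {a: AllelePseudoSequence(a, r)
              for a, r in doc["pseudo_table"].items()}
    members = [
        NetworkModel(
            wpt=np.asarray(m["wpt"]), wat=np.asarray(m["wat"]),
            bh=np.asarray(m["bh"]), wo=np.asarray(m["wo"]),
            bo=np.asarray(m["bo"]), hidden_size=m["hidden_size"],
            seed_key=tuple(m["seed_key"]), test_fold=m["test_fold"])
        for m in doc["members"]
    ]
    return Ensemble(members=members, layout=layout, enc=enc,
                    pseudo_table=pseudo, config=config)
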