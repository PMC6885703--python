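"""Semi-supervised outer training loop for multi-allele data.

The loop pre-trains a cross-validated ensemble on single-allele (SA) data
for a burn-in number of iterations.  From then on, before every training
epoch, each positive multi-allele (MA) record is annotated to one allele of
its cell line's panel: the eluted-ligand score of the record against every
panel allele is turned into a z-score against the allele's random-peptide
score distribution, and the argmax allele wins.  Negative MA records are
tagged with a random panel allele.  The annotated MA data are merged with
the SA data (respecting the cross-validation partitioning) and training
continues, re-annotating at every iteration.

Score rescaling: per allele, the mean/SD of eluted-ligand scores over
random natural core-length peptides is fitted with iterative +/-3 z-score
outlier trimming, then blended toward the across-allele averages on a
sigmoidal schedule ``w(x) = 1 / (1 + exp((x - shift)/scale))`` in the
iteration count ``x``, so the per-allele correction fades out as the MA
data are absorbed into training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import CellLinePanel, Dataset, Proteome, validate_panels
from .encoding import AllelePseudoSequence, EncodingMatrix, blosum_encoding
from .network import (
    Ensemble,
    NetworkModel,
    OUTPUT_EL,
    TrainConfig,
    TrainingArrays,
    build_training_arrays,
    encode_ninemers,
    epoch_order,
    init_network,
    run_epoch,
    stop_set_error,
    train_fold,
)

logger = logging.getLogger(__name__)


class DegenerateDistributionError(ValueError):
    """The random-peptide score distribution collapsed (sigma ~ 0)."""


class PanelLookupError(KeyError):
    pass


# ---------------------------------------------------------------------------
# Rescaling schedule and statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Schedule:
    shift: float = 75.0
    scale: float = 10.0
    burn_in: int = 20

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("schedule scale must be positive")


def blend_weight(x: float, schedule: Schedule) -> float:
    """``w = 1 / (1 + exp((x - shift)/scale))``, strictly decreasing in x."""
    if x < 0:
        raise ValueError("iteration index must be non-negative")
    return float(expit((schedule.shift - x) / schedule.scale))


@dataclass
class RescalingStats:
    """Per-allele score-distribution parameters and their blended values."""

    allele: str
    p_bar: float
    sigma: float
    p_bar_u: float = np.nan
    sigma_u: float = np.nan
    p_prime: float = np.nan
    sigma_prime: float = np.nan


def fit_trimmed_normal(scores: np.ndarray, z_cut: float = 3.0,
                       max_iter: int = 20) -> tuple[float, float]:
    """Mean/SD with iterative exclusion of |z| > z_cut outliers.

    Iterates to a fixpoint (no further exclusions) or ``max_iter`` rounds.
    """
    s = np.asarray(scores, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 scores")
    for _ in range(max_iter):
        mu = float(np.mean(s))
        sd = float(np.std(s))
        if sd < 1e-12:
            raise DegenerateDistributionError(
                f"score distribution is degenerate (sd={sd:g})")
        keep = np.abs(s - mu) <= z_cut * sd
        if keep.all():
            break
        s = s[keep]
    return mu, sd


def estimate_score_distribution(ensemble: Ensemble, allele: str,
                                proteome: Proteome, n_random: int = 10000,
                                seed: int = 0,
                                members: list[NetworkModel] | None = None,
                                ) -> tuple[float, float]:
    """Trimmed-normal (mean, SD) of ensemble EL scores on random natural
    core-length peptides."""
    rng = np.random.default_rng([seed, 0x57A7])
    peptides = proteome.sample_peptides(ensemble.layout.core_len, n_random,
                                        rng, distinct=False)
    X = encode_ninemers(peptides, ensemble.layout, ensemble.enc)
    arow = ensemble.pseudo_table[allele]
    from .encoding import encode_pseudo
    arow = encode_pseudo(arow, ensemble.layout, ensemble.enc)
    scores = _mean_single_core_scores(
        members if members is not None else ensemble.members, X, arow)
    return fit_trimmed_normal(scores)


def _mean_single_core_scores(members, X: np.ndarray,
                             arow: np.ndarray) -> np.ndarray:
    total = np.zeros(len(X))
    for m in members:
        ph = m.wat @ arow + m.bh
        h = 1.0 / (1.0 + np.exp(-(X @ m.wpt.T + ph)))
        total += 1.0 / (1.0 + np.exp(-(h @ m.wo[:, OUTPUT_EL] + m.bo[OUTPUT_EL])))
    return total / len(members)


def blend_stats(stats: dict[str, RescalingStats], x: float,
                schedule: Schedule) -> dict[str, RescalingStats]:
    """Blend per-allele stats toward the across-allele (uniform) averages.

    ``p' = w*p + (1-w)*p_u`` and ``sigma' = w*sigma + (1-w)*sigma_u`` with
    ``w = blend_weight(x)``; the uniform values are the plain averages over
    all alleles present in the MA data.
    """
    w = blend_weight(x, schedule)
    p_u = float(np.mean([s.p_bar for s in stats.values()]))
    s_u = float(np.mean([s.sigma for s in stats.values()]))
    out = {}
    for allele, s in stats.items():
        out[allele] = replace(
            s, p_bar_u=p_u, sigma_u=s_u,
            p_prime=w * s.p_bar + (1.0 - w) * p_u,
            sigma_prime=w * s.sigma + (1.0 - w) * s_u)
    return out


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _annotate_arrays(arrays: TrainingArrays, ma_idx: np.ndarray,
                     panel_of_label: dict[str, tuple[str, ...]],
                     nets_by_fold: dict[int, list[NetworkModel]],
                     stats_by_fold: dict[int, dict[str, RescalingStats]] | None,
                     iteration: int, seed: int,
                     ensemble_helper: "Ensemble",
                     score_scale: dict[str, float] | None = None) -> pd.DataFrame:
    """Assign one allele to every MA record, in place on ``allele_idx``.

    Positives go to the allele with the highest (rescaled) EL score, ties
    to the lexicographically smallest allele name; negatives to a uniformly
    random panel allele re-drawn with an iteration-derived seed.
    """
    rows = []
    neg_rng = np.random.default_rng([seed, 0xA9, iteration])
    pos_mask = arrays.is_positive[ma_idx]
    # negatives: iterate in global index order for determinism
    for t in ma_idx[~pos_mask]:
        panel = panel_of_label[arrays.labels[t]]
        choice = panel[int(neg_rng.integers(0, len(panel)))]
        arrays.allele_idx[t] = arrays.allele_index(choice)
        rows.append((int(t), choice, np.nan, np.nan))

    pos_idx = ma_idx[pos_mask]
    folds = arrays.partition[pos_idx]
    for fold in sorted(nets_by_fold):
        sel = pos_idx[folds == fold]
        if len(sel) == 0:
            continue
        alleles = sorted({a for t in sel
                          for a in panel_of_label[arrays.labels[t]]})
        score_cols = {}
        for allele in alleles:
            raw = ensemble_helper.batch_predict(
                arrays, sel, allele, "EL", members=nets_by_fold[fold])
            if score_scale is not None:
                raw = raw * score_scale.get(allele, 1.0)
            if stats_by_fold is not None:
                st = stats_by_fold[fold][allele]
                score_cols[allele] = ((raw - st.p_prime) / st.sigma_prime, raw)
            else:
                score_cols[allele] = (raw, raw)
        for k, t in enumerate(sel):
            panel = sorted(panel_of_label[arrays.labels[t]])
            best_a, best_z = None, -np.inf
            for a in panel:  # sorted order + strict '>' = lexicographic ties
                z = float(score_cols[a][0][k])
                if z > best_z:
                    best_a, best_z = a, z
            arrays.allele_idx[t] = arrays.allele_index(best_a)
            rows.append((int(t), best_a, float(score_cols[best_a][1][k]),
                         best_z))
    df = pd.DataFrame(rows, columns=["index", "annotation", "raw_score",
                                     "z_score"]).set_index("index").sort_index()
    df["iteration"] = iteration
    return df


def annotate_ma(ensemble: Ensemble, ma: Dataset,
                panels: dict[str, CellLinePanel],
                stats: dict[str, RescalingStats] | None,
                iteration: int, seed: int = 0) -> pd.DataFrame:
    """Annotate an MA dataset with a trained ensemble (all members).

    Returns a frame with columns peptide, label, annotation, raw_score,
    z_score, iteration.  Training uses the fold-aware fast path instead.
    """
    for label in ma.records["label"].unique():
        if label not in panels:
            raise PanelLookupError(f"no panel for MA label {label!r}")
    arrays = build_training_arrays(ma.records, ensemble.pseudo_table,
                                   ensemble.layout, ensemble.enc)
    panel_of_label = {n: p.alleles for n, p in panels.items()}
    nets_by_fold = {-1: ensemble.members}
    arrays.partition[:] = -1
    stats_by_fold = {-1: stats} if stats is not None else None
    ann = _annotate_arrays(arrays, np.arange(arrays.n_records),
                           panel_of_label, nets_by_fold, stats_by_fold,
                           iteration, seed, ensemble)
    out = ma.records[["peptide", "label"]].copy()
    out["annotation"] = ann["annotation"]
    out["raw_score"] = ann["raw_score"]
    out["z_score"] = ann["z_score"]
    out["iteration"] = iteration
    return out


# ---------------------------------------------------------------------------
# The outer loop
# ---------------------------------------------------------------------------

@dataclass
class MARun:
    """Everything produced by one training run."""

    ensemble: Ensemble
    annotation: pd.DataFrame          # one row per MA record
    history: list[dict]
    arrays: TrainingArrays
    records: pd.DataFrame             # SA + MA records in array order
    seed: int


def run_nnalign_ma(sa: Dataset, ma: Dataset | None,
                   panels: dict[str, CellLinePanel],
                   pseudo_table: dict[str, AllelePseudoSequence],
                   proteome: Proteome, config: TrainConfig, seed: int,
                   enc: EncodingMatrix | None = None,
                   score_scale: dict[str, float] | None = None) -> MARun:
    """Train the full semi-supervised ensemble.

    ``sa`` holds both BA and EL single-allele records (``assay`` column
    distinguishes them); ``ma`` may be None or empty, in which case the run
    degenerates to plain SA-only training with an identical weight
    trajectory under equal seeds.  Partitions must be precomputed jointly
    on SA and MA.

    ``score_scale`` multiplies the raw EL scores of selected alleles during
    annotation and stats estimation only (never during weight updates) --
    an experimental hook emulating alleles whose prediction values are
    systematically depressed relative to the rest of the panel.
    """
    enc = enc or blosum_encoding()
    if len(sa) == 0:
        raise ValueError("SA dataset must be non-empty")
    ma_records = ma.records if ma is not None and len(ma) else None
    if ma_records is not None:
        validate_panels(panels, pseudo_table)
        for label in ma_records["label"].unique():
            if label not in panels:
                raise PanelLookupError(f"no panel for MA label {label!r}")

    sa_alleles = sorted(set(sa.records["label"]))
    panel_alleles = sorted({a for p in panels.values() for a in p.alleles}) \
        if ma_records is not None else []
    for a in sa_alleles + panel_alleles:
        if a not in pseudo_table:
            raise KeyError(f"allele {a} missing from pseudo-sequence table")
    allele_names = sorted(set(sa_alleles) | set(panel_alleles))

    pseudo_len = len(next(iter(pseudo_table.values())).residues)
    layout = config.layout(pseudo_len)

    combined = pd.concat([sa.records] + (
        [ma_records] if ma_records is not None else []), ignore_index=True)
    arrays = build_training_arrays(combined, pseudo_table, layout, enc,
                                   allele_names=allele_names)
    n_ma = int(arrays.is_ma.sum())
    ma_idx = np.flatnonzero(arrays.is_ma)
    panel_of_label = ({n: p.alleles for n, p in panels.items()}
                      if n_ma else {})
    ma_allele_names = panel_alleles

    schedule = Schedule(shift=config.rescale_shift,
                        scale=config.rescale_scale, burn_in=config.burn_in)

    # one network per (fold, hidden size, seed index)
    nets: list[NetworkModel] = []
    for fold in range(config.n_partitions):
        for si in range(len(config.hidden_sizes)):
            for sj in range(config.seeds_per_size):
                key = (seed, fold, si, sj)
                nets.append(init_network(layout, config.hidden_sizes[si],
                                         key, test_fold=fold))
    nets_by_fold = {f: [m for m in nets if m.test_fold == f]
                    for f in range(config.n_partitions)}

    sa_mask = ~arrays.is_ma
    train_sa = {f: np.flatnonzero(sa_mask & (arrays.partition != f))
                for f in range(config.n_partitions)}
    train_all = {f: np.flatnonzero(arrays.partition != f)
                 for f in range(config.n_partitions)}
    stop_sa = {f: np.flatnonzero(sa_mask & (arrays.partition == f))
               for f in range(config.n_partitions)}
    stop_all = {f: np.flatnonzero(arrays.partition == f)
                for f in range(config.n_partitions)}

    ensemble = Ensemble(members=nets, layout=layout, enc=enc,
                        pseudo_table={a: pseudo_table[a] for a in allele_names},
                        config=config)

    best_err = {id(m): np.inf for m in nets}
    best_w: dict[int, tuple] = {}
    history: list[dict] = []
    last_ann: pd.DataFrame | None = None

    for it in range(1, config.n_iterations + 1):
        annotating = n_ma > 0 and it > config.burn_in
        if annotating:
            stats_by_fold = None
            if config.rescale:
                stats_by_fold = _per_fold_stats(
                    arrays, ma_allele_names, nets_by_fold, proteome, layout,
                    enc, config, ensemble, schedule, it, seed, score_scale)
            last_ann = _annotate_arrays(
                arrays, ma_idx, panel_of_label, nets_by_fold, stats_by_fold,
                it, seed, ensemble, score_scale)
        for m in nets:
            f = m.test_fold
            idx = train_all[f] if annotating else train_sa[f]
            order = epoch_order(m.seed_key, it, idx)
            run_epoch(m, arrays, order, config.learning_rate)
        entry = {"iteration": it,
                 "w": blend_weight(it, schedule) if n_ma else np.nan,
                 "annotating": annotating}
        if config.early_stopping:
            errs = []
            for m in nets:
                f = m.test_fold
                sidx = stop_all[f] if annotating else stop_sa[f]
                err = stop_set_error(m, arrays, sidx)
                errs.append(err)
                if err < best_err[id(m)]:
                    best_err[id(m)] = err
                    best_w[id(m)] = m.copy_weights()
            entry["stop_error"] = float(np.mean(errs))
        if annotating and last_ann is not None:
            counts = last_ann.loc[
                last_ann.index[arrays.is_positive[last_ann.index]],
                "annotation"].value_counts()
            entry["n_annotated"] = counts.to_dict()
        history.append(entry)
        logger.debug("iteration %d: %s", it, entry)

    if config.early_stopping:
        for m in nets:
            if id(m) in best_w:
                m.set_weights(best_w[id(m)])

    # final cross-validated annotation with the trained weights
    annotation = pd.DataFrame()
    if n_ma:
        stats_by_fold = None
        if config.rescale:
            stats_by_fold = _per_fold_stats(
                arrays, ma_allele_names, nets_by_fold, proteome, layout, enc,
                config, ensemble, schedule, config.n_iterations + 1, seed,
                score_scale)
        final = _annotate_arrays(arrays, ma_idx, panel_of_label, nets_by_fold,
                                 stats_by_fold, config.n_iterations + 1, seed,
                                 ensemble, score_scale)
        annotation = combined.loc[final.index, ["peptide", "target", "label",
                                                "partition"]].copy()
        annotation["annotation"] = final["annotation"]
        annotation["raw_score"] = final["raw_score"]
        annotation["z_score"] = final["z_score"]
        annotation["iteration"] = final["iteration"]
        # rows are in combined order (SA block first), so after the reset the
        # frame aligns row-for-row with the MA dataset
        annotation = annotation.reset_index(drop=True)

    return MARun(ensemble=ensemble, annotation=annotation, history=history,
                 arrays=arrays, records=combined, seed=seed)


def _per_fold_stats(arrays, ma_allele_names, nets_by_fold, proteome, layout,
                    enc, config, ensemble, schedule, iteration, seed,
                    score_scale=None):
    """Fresh per-(fold, allele) rescaling stats for one annotation round."""
    rng = np.random.default_rng([seed, 0x57A7, iteration])
    peptides = proteome.sample_peptides(layout.core_len,
                                        config.n_rescale_peptides, rng,
                                        distinct=False)
    X = encode_ninemers(peptides, layout, enc)
    stats_by_fold: dict[int, dict[str, RescalingStats]] = {}
    for fold, members in nets_by_fold.items():
        stats = {}
        for allele in ma_allele_names:
            arow = arrays.allele_enc[arrays.allele_index(allele)]
            scores = _mean_single_core_scores(members, X, arow)
            if score_scale is not None:
                scores = scores * score_scale.get(allele, 1.0)
            mu, sd = fit_trimmed_normal(scores)
            stats[allele] = RescalingStats(allele=allele, p_bar=mu, sigma=sd)
        stats_by_fold[fold] = blend_stats(stats, iteration, schedule)
    return stats_by_fold


def train_sa_ensemble(sa: Dataset,
                      pseudo_table: dict[str, AllelePseudoSequence],
                      config: TrainConfig, seed: int,
                      enc: EncodingMatrix | None = None) -> MARun:
    """Plain SA-only cross-validated training (no MA loop).

    Net-major orchestration via :func:`train_fold`; with the same seed this
    reproduces ``run_nnalign_ma(sa, ma=None, ...)`` bit for bit.
    """
    enc = enc or blosum_encoding()
    allele_names = sorted(set(sa.records["label"]))
    pseudo_len = len(next(iter(pseudo_table.values())).residues)
    layout = config.layout(pseudo_len)
    arrays = build_training_arrays(sa.records, pseudo_table, layout, enc,
                                   allele_names=allele_names)
    nets = []
    for fold in range(config.n_partitions):
        train_idx = np.flatnonzero(arrays.partition != fold)
        stop_idx = np.flatnonzero(arrays.partition == fold)
        for si in range(len(config.hidden_sizes)):
            for sj in range(config.seeds_per_size):
                key = (seed, fold, si, sj)
                nets.append(train_fold(arrays, train_idx, stop_idx,
                                       config.hidden_sizes[si], config, key,
                                       test_fold=fold))
    ensemble = Ensemble(members=nets, layout=layout, enc=enc,
                        pseudo_table={a: pseudo_table[a] for a in allele_names},
                        config=config)
    return MARun(ensemble=ensemble, annotation=pd.DataFrame(), history=[],
                 arrays=arrays, records=sa.records, seed=seed)


# ---------------------------------------------------------------------------
# Out-of-fold prediction for evaluation
# ---------------------------------------------------------------------------

def motif_for_allele(ensemble: Ensemble, allele: str, proteome: Proteome,
                     n_random: int | None = None,
                     top_frac: float | None = None, seed: int = 0):
    """Recovered motif from the top-scoring fraction of random natural
    core-length peptides (the default motif-construction mode)."""
    from .encoding import encode_pseudo
    from .metrics import motif_from_cores

    config = ensemble.config
    n = n_random or config.motif_random_peptides
    tf = top_frac or config.motif_top_frac
    rng = np.random.default_rng([seed, 0x3070])
    peptides = proteome.sample_peptides(ensemble.layout.core_len, n, rng,
                                        distinct=False)
    X = encode_ninemers(peptides, ensemble.layout, ensemble.enc)
    arow = encode_pseudo(ensemble.pseudo_table[allele], ensemble.layout,
                         ensemble.enc)
    scores = _mean_single_core_scores(ensemble.members, X, arow)
    k = max(1, int(round(n * tf)))
    top = np.argsort(-scores, kind="stable")[:k]
    return motif_from_cores([peptides[i] for i in top], allele=allele)


def motif_from_annotated(run: MARun, allele: str):
    """Motif from the predicted binding cores of the MA ligands annotated
    to ``allele`` (cross-validated, as used for per-cell-line logos)."""
    from . import _kernels
    from .metrics import motif_from_cores
    from .network import OUTPUT_EL

    arrays = run.arrays
    ann = run.annotation
    sel_rows = ann.index[(ann["target"] > 0) & (ann["annotation"] == allele)]
    if len(sel_rows) == 0:
        raise ValueError(f"no ligands annotated to {allele}")
    n_sa = int((~arrays.is_ma).sum())
    indices = np.asarray(sel_rows, dtype=np.int64) + n_sa
    arow = arrays.allele_enc[arrays.allele_index(allele)]
    cores = []
    for fold in sorted(set(arrays.partition[indices])):
        members = run.ensemble.fold_members(int(fold))
        sub = indices[arrays.partition[indices] == fold]
        starts = np.ascontiguousarray(arrays.core_start[sub])
        counts = np.ascontiguousarray(arrays.core_count[sub])
        votes = np.zeros((len(sub), int(counts.max())))
        for m in members:
            _, best = _kernels.batch_scores(
                m.wpt, m.wat, m.bh, m.wo, m.bo,
                arrays.core_feats, starts, counts, arow, OUTPUT_EL)
            for k, b in enumerate(best):
                votes[k, int(b) - starts[k]] += 1
        for k in range(len(sub)):
            cores.append(arrays.cores[starts[k] + int(np.argmax(votes[k]))])
    return motif_from_cores(cores, allele=allele)


def out_of_fold_scores(run: MARun, panels: dict[str, CellLinePanel],
                       assay: str = "EL") -> pd.DataFrame:
    """Cross-validated prediction score per record of the given assay.

    SA records are scored against their own allele; MA records get the max
    score over their panel.  Every record is scored only by members whose
    training folds exclude its partition.
    """
    arrays = run.arrays
    ensemble = run.ensemble
    sel_mask = (run.records["assay"] == assay).to_numpy()
    out = run.records[sel_mask].copy()
    idx_all = np.flatnonzero(sel_mask)
    scores = np.full(len(idx_all), np.nan)
    pos_of = {int(t): k for k, t in enumerate(idx_all)}
    for fold in sorted(set(arrays.partition)):
        members = ensemble.fold_members(int(fold))
        sel = idx_all[arrays.partition[idx_all] == fold]
        if len(sel) == 0:
            continue
        sa_sel = sel[~arrays.is_ma[sel]]
        for allele in sorted(set(arrays.labels[sa_sel])):
            sub = sa_sel[arrays.labels[sa_sel] == allele]
            s = ensemble.batch_predict(arrays, sub, allele, assay,
                                       members=members)
            for t, v in zip(sub, s):
                scores[pos_of[int(t)]] = v
        ma_sel = sel[arrays.is_ma[sel]]
        if len(ma_sel):
            for label in sorted(set(arrays.labels[ma_sel])):
                sub = ma_sel[arrays.labels[ma_sel] == label]
                best = np.full(len(sub), -np.inf)
                for allele in panels[label].alleles:
                    s = ensemble.batch_predict(arrays, sub, allele, assay,
                                               members=members)
                    best = np.maximum(best, s)
                for t, v in zip(sub, best):
                    scores[pos_of[int(t)]] = v
    out["score"] = scores
    return out


def out_of_fold_allele_scores(run: MARun, indices: np.ndarray, allele: str,
                              assay: str = "EL") -> np.ndarray:
    """Out-of-fold scores of specific records against one fixed allele."""
    arrays = run.arrays
    scores = np.full(len(indices), np.nan)
    for fold in sorted(set(arrays.partition[indices])):
        members = run.ensemble.fold_members(int(fold))
        mask = arrays.partition[indices] == fold
        sub = indices[mask]
        scores[mask] = run.ensemble.batch_predict(arrays, sub, allele, assay,
                                                  members=members)
    return scores
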