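"""Evaluation statistics: ROC areas, epitope ranking, motif construction
and comparison, cluster cleanness and locus peptidome shares."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .encoding import ALPHABET, AA_INDEX, N_RESIDUES

logger = logging.getLogger(__name__)


class SingleClassError(ValueError):
    pass


def _check_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise SingleClassError("need both positive and negative examples")
    return labels, ~labels


def auc(scores, labels) -> float:
    """ROC AUC via the normalized Mann-Whitney U statistic (ties 0.5)."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_classes(labels)
    ranks = sps.rankdata(scores)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """ROC vertices (fpr, tpr) with tied scores collapsed to one vertex."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_classes(labels)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = pos[order]
    boundary = np.flatnonzero(np.diff(s)) + 1
    cuts = np.concatenate([boundary, [len(s)]])
    tp = np.cumsum(y)[cuts - 1]
    fp = cuts - tp
    tpr = np.concatenate([[0.0], tp / pos.sum()])
    fpr = np.concatenate([[0.0], fp / neg.sum()])
    return fpr, tpr


def auc01(scores, labels, max_fpr: float = 0.1) -> float:
    """Area under the ROC curve up to ``max_fpr``, normalized so a perfect
    classifier scores 1."""
    fpr, tpr = roc_curve(scores, labels)
    cut = np.searchsorted(fpr, max_fpr, side="right")
    fx = fpr[:cut]
    fy = tpr[:cut]
    if cut < len(fpr) and fpr[cut - 1] < max_fpr:
        # linear interpolation at the cut point
        x0, x1 = fpr[cut - 1], fpr[cut]
        y0, y1 = tpr[cut - 1], tpr[cut]
        y_cut = y0 + (y1 - y0) * (max_fpr - x0) / (x1 - x0)
        fx = np.concatenate([fx, [max_fpr]])
        fy = np.concatenate([fy, [y_cut]])
    return float(np.trapezoid(fy, fx) / max_fpr)


def pearson(a, b) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("undefined correlation: zero-variance input")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Epitope ranking (Frank)
# ---------------------------------------------------------------------------

def digest(antigen: str, lengths) -> list[str]:
    """Unique overlapping substrings of the given lengths, in first-seen
    order along the protein."""
    seen = set()
    out = []
    for k in lengths:
        for s in range(len(antigen) - k + 1):
            pep = antigen[s:s + k]
            if pep not in seen:
                seen.add(pep)
                out.append(pep)
    return out


def frank(epitope: str, antigen: str, score_fn, lengths) -> float:
    """Fraction of digested peptides scoring strictly above the epitope.

    The denominator excludes the epitope itself, so the top-ranked epitope
    scores exactly 0 and a random scorer is 0.5 in expectation.
    """
    peptides = digest(antigen, lengths)
    if epitope not in peptides:
        raise ValueError(f"epitope {epitope!r} absent from antigen")
    scores = np.asarray(score_fn(peptides), dtype=float)
    e = scores[peptides.index(epitope)]
    others = np.delete(scores, peptides.index(epitope))
    if len(others) == 0:
        raise ValueError("antigen digests to the epitope only")
    return float((others > e).sum() / len(others))


# ---------------------------------------------------------------------------
# Concatenated cross-validation evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    per_label: pd.DataFrame       # label, origin, n_pos, n_neg, auc, auc01
    ba_per_allele: pd.DataFrame   # allele, n, pcc
    ppv: pd.DataFrame | None = None
    locus_shares: pd.DataFrame | None = None


def evaluate_concatenated(el_predictions: pd.DataFrame,
                          ba_predictions: pd.DataFrame | None = None,
                          ) -> EvalReport:
    """Per-label AUC/AUC0.1 on concatenated out-of-fold EL predictions,
    plus per-allele Pearson correlation on BA predictions.

    ``el_predictions`` needs columns label, target, score; labels with a
    single class are skipped with a log entry.
    """
    rows = []
    for label, grp in el_predictions.groupby("label", sort=True):
        y = grp["target"].to_numpy() > 0
        s = grp["score"].to_numpy()
        if y.all() or not y.any():
            logger.info("label %s skipped: single class", label)
            continue
        rows.append({
            "label": label,
            "origin": grp["origin"].iloc[0] if "origin" in grp else "",
            "n_pos": int(y.sum()),
            "n_neg": int((~y).sum()),
            "auc": auc(s, y),
            "auc01": auc01(s, y),
        })
    per_label = pd.DataFrame(rows)
    ba_rows = []
    if ba_predictions is not None and len(ba_predictions):
        for allele, grp in ba_predictions.groupby("label", sort=True):
            if len(grp) < 3 or grp["target"].std() == 0:
                continue
            ba_rows.append({"allele": allele, "n": len(grp),
                            "pcc": pearson(grp["score"], grp["target"])})
    return EvalReport(per_label=per_label,
                      ba_per_allele=pd.DataFrame(ba_rows))


def ppv_per_motif(cell_records: pd.DataFrame,
                  allele_scores: dict[str, np.ndarray],
                  top_frac: float = 0.95) -> dict[str, float]:
    """Cluster cleanness for one cell line.

    For each allele, N = number of positives annotated to it; all records
    of the cell line are ranked by their score against that allele and the
    PPV is the fraction of true ligands among the top ``floor(N * 0.95)``.
    Alleles with N = 0 are skipped.
    """
    targets = cell_records["target"].to_numpy() > 0
    annotations = cell_records["annotation"].to_numpy()
    out = {}
    for allele, scores in sorted(allele_scores.items()):
        n = int((targets & (annotations == allele)).sum())
        top = int(np.floor(n * top_frac))
        if top == 0:
            logger.info("PPV: allele %s skipped (no assigned ligands)", allele)
            continue
        order = np.argsort(-np.asarray(scores), kind="stable")
        out[allele] = float(targets[order[:top]].sum() / top)
    return out


def locus_shares(annotation: pd.DataFrame, locus_map: dict[str, str]
                 ) -> pd.DataFrame:
    """Per cell line, the fraction of positive ligands annotated to each
    locus.  Fractions sum to 1 per cell line."""
    pos = annotation[annotation["target"] > 0]
    missing = set(pos["annotation"]) - set(locus_map)
    if missing:
        raise KeyError(f"alleles missing from locus map: {sorted(missing)}")
    loci = sorted(set(locus_map.values()))
    rows = []
    for label, grp in pos.groupby("label", sort=True):
        counts = grp["annotation"].map(locus_map).value_counts()
        total = len(grp)
        rows.append({"cell_line": label,
                     **{l: counts.get(l, 0) / total for l in loci}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Motifs
# ---------------------------------------------------------------------------

@dataclass
class Motif:
    """Position x residue frequency matrix of a binding core, with the
    KL-weighted (information content) version used for logos."""

    allele: str
    freq: np.ndarray          # (core_len, 20), row-stochastic
    kl: np.ndarray            # (core_len, 20), non-negative
    support: int

    def __post_init__(self):
        if not np.allclose(self.freq.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("motif rows must sum to 1")


def motif_from_cores(cores: list[str], allele: str = "",
                     pseudocount: float = 1.0,
                     background: np.ndarray | None = None) -> Motif:
    """Frequency/KL motif from aligned core strings.

    Frequencies are smoothed with a flat pseudocount weighted
    ``pseudocount / (support + pseudocount)``; wildcard positions are
    ignored.  KL weights distribute the per-position information content
    ``log2(20) - H(p)`` (relative to a uniform background) over residues by
    frequency.
    """
    if not cores:
        raise ValueError("no cores to build a motif from")
    core_len = len(cores[0])
    if any(len(c) != core_len for c in cores):
        raise ValueError("cores have unequal lengths")
    bg = np.full(N_RESIDUES, 1.0 / N_RESIDUES) if background is None \
        else np.asarray(background, dtype=float)
    counts = np.zeros((core_len, N_RESIDUES))
    for core in cores:
        for p, ch in enumerate(core):
            i = AA_INDEX[ch]
            if i < N_RESIDUES:
                counts[p, i] += 1.0
    n = counts.sum(axis=1, keepdims=True)
    n[n == 0] = 1.0
    raw = counts / n
    freq = (counts + pseudocount * bg) / (n + pseudocount)
    freq /= freq.sum(axis=1, keepdims=True)
    info = np.log2(N_RESIDUES) + (freq * np.log2(freq)).sum(axis=1)
    kl = freq * np.maximum(info, 0.0)[:, None]
    return Motif(allele=allele, freq=freq, kl=kl, support=len(cores))


def motif_pcc(a: Motif, b) -> float:
    """Pearson correlation of two flattened core_len x 20 frequency
    matrices (``b`` may be a Motif or a raw matrix)."""
    bm = b.freq if isinstance(b, Motif) else np.asarray(b, dtype=float)
    if a.freq.shape != bm.shape:
        raise ValueError("motif shapes differ")
    return pearson(a.freq, bm)


def write_motif(motif: Motif, path) -> None:
    df = pd.DataFrame(motif.freq, columns=list(ALPHABET))
    df.insert(0, "position", np.arange(1, len(df) + 1))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def build_motif_random(score_and_core_fn, proteome, core_len: int,
                       allele: str, n_random: int = 200000,
                       top_frac: float = 0.001, seed: int = 0,
                       min_support: int = 20) -> Motif:
    """Motif from the argmax binding cores of the top ``top_frac`` scoring
    random natural core-length peptides."""
    rng = np.random.default_rng([seed, 0x3070])
    peptides = proteome.sample_peptides(core_len, n_random, rng,
                                        distinct=False)
    scores, cores = score_and_core_fn(peptides)
    k = max(1, int(round(n_random * top_frac)))
    top = np.argsort(-np.asarray(scores), kind="stable")[:k]
    motif = motif_from_cores([cores[i] for i in top], allele=allele)
    if motif.support < min_support:
        logger.warning("motif for %s has low support (%d)", allele,
                       motif.support)
    return motif
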