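"""Peptide dataset IO, target transforms, negative enrichment and
cross-validation partitioning.

Datasets are thin wrappers around a pandas DataFrame with one row per
peptide record.  Canonical columns::

    peptide    str   sequence over the 21-letter alphabet
    target     float EL: {0, 1}; BA: [0, 1]
    label      str   allele name (SA) or cell-line id (MA)
    assay      str   'BA' or 'EL'
    origin     str   'SA' or 'MA'
    partition  int   cross-validation fold, -1 before assignment
    annotation str   allele chosen for an MA record, '' before annotation

Extra columns (e.g. a hidden ground-truth allele in synthetic fixtures)
are carried through untouched.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .encoding import AA_INDEX, validate_sequence

logger = logging.getLogger(__name__)

CLASS_I_BOUNDS = (8, 14)
CLASS_II_BOUNDS = (13, 21)

COLUMNS = ["peptide", "target", "label", "assay", "origin", "partition",
           "annotation"]


class ParseError(ValueError):
    pass


class SamplingError(ValueError):
    pass


@dataclass
class Dataset:
    """A validated peptide table plus its task metadata."""

    records: pd.DataFrame
    length_bounds: tuple[int, int] = CLASS_I_BOUNDS
    task: str = "classI"

    def __post_init__(self):
        df = self.records
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"missing dataset columns: {missing}")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def peptides(self) -> pd.Series:
        return self.records["peptide"]

    def copy(self) -> "Dataset":
        return Dataset(self.records.copy(), self.length_bounds, self.task)


def make_records(peptides, targets, labels, assay: str, origin: str,
                 **extra) -> pd.DataFrame:
    n = len(peptides)
    df = pd.DataFrame({
        "peptide": list(peptides),
        "target": np.asarray(targets, dtype=float),
        "label": list(labels) if not isinstance(labels, str) else [labels] * n,
        "assay": assay,
        "origin": origin,
        "partition": -1,
        "annotation": "",
    })
    for k, v in extra.items():
        df[k] = v
    return df


def _validate_records(df: pd.DataFrame, assay: str, bounds) -> None:
    lo, hi = bounds
    bad = ~df["target"].between(0.0, 1.0)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"target {df['target'].iloc[i]} outside [0, 1] (row {i})")
    if assay == "EL":
        non_binary = ~df["target"].isin([0.0, 1.0])
        if non_binary.any():
            i = int(np.flatnonzero(non_binary.to_numpy())[0])
            raise ParseError(
                f"EL target {df['target'].iloc[i]} not in {{0, 1}} (row {i})")
    for pep in df["peptide"]:
        validate_sequence(pep)


def read_peptide_table(path, assay: str, origin: str,
                       length_bounds=CLASS_I_BOUNDS,
                       task: str = "classI") -> Dataset:
    """Read a ``peptide<TAB>target<TAB>label`` table into a Dataset.

    Rows whose peptide length falls outside ``length_bounds`` are dropped
    with a logged count; malformed rows raise with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(parts)}")
            pep, target, label = parts
            try:
                t = float(target)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad target {target!r}") from exc
            rows.append((pep, t, label))
    df = make_records([r[0] for r in rows], [r[1] for r in rows],
                      [r[2] for r in rows], assay=assay, origin=origin)
    lo, hi = length_bounds
    lengths = df["peptide"].str.len()
    keep = lengths.between(lo, hi)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d peptides outside length bounds [%d, %d]",
                    path, n_dropped, lo, hi)
    df = df[keep].reset_index(drop=True)
    _validate_records(df, assay, length_bounds)
    return Dataset(df, length_bounds=length_bounds, task=task)


def write_peptide_table(dataset: Dataset, path) -> None:
    dataset.records[["peptide", "target", "label"]].to_csv(
        path, sep="\t", header=False, index=False)


def write_predictions(df: pd.DataFrame, path) -> None:
    """Write a prediction table (peptide, label, annotation, scores...)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Binding-affinity target transform
# ---------------------------------------------------------------------------

_IC50_MAX = 50000.0


def ba_transform(ic50_nM: float) -> float:
    """Map an IC50 in nM to ``1 - log(ic50)/log(50000)``, clipped to [0, 1]."""
    if ic50_nM <= 0:
        raise ValueError(f"non-positive IC50: {ic50_nM}")
    return float(np.clip(1.0 - math.log(ic50_nM) / math.log(_IC50_MAX), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Proteomes and random-natural negatives
# ---------------------------------------------------------------------------

@dataclass
class Proteome:
    """Named protein sequences used for random-natural peptide sampling."""

    sequences: dict[str, str]

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("empty proteome")
        for seq in self.sequences.values():
            validate_sequence(seq)
        names = sorted(self.sequences)
        self._names = names
        self._seqs = [self.sequences[n] for n in names]
        self._lengths = np.array([len(s) for s in self._seqs])

    @classmethod
    def from_fasta(cls, path) -> "Proteome":
        seqs = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(path), "fasta")}
        return cls(seqs)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name in self._names:
                fh.write(f">{name}\n{self.sequences[name]}\n")

    def sample_peptides(self, length: int, n: int,
                        rng: np.random.Generator,
                        exclude: set[str] | None = None,
                        distinct: bool = True) -> list[str]:
        """Sample ``n`` substrings of ``length`` uniformly over all valid
        start positions.  With ``distinct`` (the default) sampling is
        without replacement and collisions with ``exclude`` are resampled;
        with ``distinct=False`` draws are independent (used for the large
        random-peptide pools of score rescaling and motif construction)."""
        starts = self._lengths - length + 1
        valid = starts > 0
        if not valid.any():
            raise SamplingError(
                f"no proteome sequence long enough for length {length}")
        weights = np.where(valid, starts, 0).astype(float)
        weights /= weights.sum()
        if not distinct:
            seq_idx = rng.choice(len(self._seqs), size=n, p=weights)
            offsets = rng.random(n)
            return [self._seqs[i][int(o * starts[i]):
                                  int(o * starts[i]) + length]
                    for i, o in zip(seq_idx, offsets)]
        chosen: list[str] = []
        seen = set() if exclude is None else set(exclude)
        attempts = 0
        max_attempts = 200 * max(n, 1)
        while len(chosen) < n:
            if attempts >= max_attempts:
                raise SamplingError(
                    f"could not sample {n} distinct {length}mers from proteome")
            attempts += 1
            i = rng.choice(len(self._seqs), p=weights)
            s = int(rng.integers(0, starts[i]))
            pep = self._seqs[i][s:s + length]
            if pep in seen:
                continue
            seen.add(pep)
            chosen.append(pep)
        return chosen


NEGATIVE_FOLD = 5  # negatives per length = 5 x modal positive-length count


def enrich_negatives(positives: Dataset, proteome: Proteome,
                     seed: int) -> Dataset:
    """Append random-natural negatives to an eluted-ligand dataset.

    For every label independently: find the most abundant positive peptide
    length, and for *each* length inside the bounds append exactly
    ``5 x`` that modal count of uniformly sampled proteome substrings with
    target 0.  Sampling is without replacement within a (label, length)
    stratum and avoids collisions with same-label positives.
    """
    df = positives.records
    if len(df) == 0 or not (df["target"] > 0).any():
        raise ValueError("no positive records to enrich")
    lo, hi = positives.length_bounds
    parts = [df]
    for label in sorted(df["label"].unique()):
        sub = df[(df["label"] == label) & (df["target"] > 0)]
        if len(sub) == 0:
            continue
        counts = sub["peptide"].str.len().value_counts()
        modal = int(counts.max())
        origin = sub["origin"].iloc[0]
        pos_set = set(sub["peptide"])
        rng = np.random.default_rng([seed, _stable_hash(label)])
        for length in range(lo, hi + 1):
            negs = proteome.sample_peptides(length, NEGATIVE_FOLD * modal,
                                            rng, exclude=pos_set)
            neg_df = make_records(negs, np.zeros(len(negs)), label,
                                  assay="EL", origin=origin)
            parts.append(neg_df)
    out = pd.concat(parts, ignore_index=True)
    # fill extra columns (e.g. hidden ground truth) for the negatives
    for col in out.columns:
        if col not in COLUMNS and out[col].dtype == object:
            out[col] = out[col].fillna("")
    return Dataset(out, positives.length_bounds, positives.task)


def _stable_hash(text: str) -> int:
    h = 2166136261
    for ch in text.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h


# ---------------------------------------------------------------------------
# SA/MA deduplication
# ---------------------------------------------------------------------------

def dedupe_sa_vs_ma(sa: Dataset, ma: Dataset) -> Dataset:
    """Remove from SA every record whose peptide occurs in MA (MA untouched)."""
    ma_peps = set(ma.peptides)
    keep = ~sa.peptides.isin(ma_peps)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("dedupe: removed %d SA records duplicated in MA", n_removed)
    return Dataset(sa.records[keep].reset_index(drop=True),
                   sa.length_bounds, sa.task)


# ---------------------------------------------------------------------------
# Common-motif cross-validation partitioning
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_by_shared_kmers(peptides: list[str], motif_len: int) -> np.ndarray:
    """Cluster ids such that peptides sharing any ungapped ``motif_len``-mer
    end up in the same cluster (transitive closure)."""
    uf = _UnionFind(len(peptides))
    kmer_owner: dict[str, int] = {}
    for i, pep in enumerate(peptides):
        if len(pep) < motif_len:
            raise ValueError(
                f"motif length {motif_len} exceeds peptide {pep!r}")
        for s in range(len(pep) - motif_len + 1):
            kmer = pep[s:s + motif_len]
            j = kmer_owner.setdefault(kmer, i)
            if j != i:
                uf.union(i, j)
    roots = np.array([uf.find(i) for i in range(len(peptides))])
    _, ids = np.unique(roots, return_inverse=True)
    return ids


def assign_clusters_to_partitions(cluster_ids: np.ndarray, n_parts: int,
                                  seed: int) -> np.ndarray:
    """Greedy balanced assignment: largest cluster first into the currently
    smallest partition; the seed shuffles the order among equal-size
    clusters (deterministically)."""
    rng = np.random.default_rng([seed, 0x7CF5])
    n_clusters = int(cluster_ids.max()) + 1 if len(cluster_ids) else 0
    sizes = np.bincount(cluster_ids, minlength=n_clusters)
    order = rng.permutation(n_clusters)
    order = order[np.argsort(-sizes[order], kind="stable")]
    loads = np.zeros(n_parts, dtype=int)
    cluster_part = np.empty(n_clusters, dtype=int)
    for c in order:
        p = int(np.argmin(loads))  # ties -> lowest partition index
        cluster_part[c] = p
        loads[p] += sizes[c]
    return cluster_part[cluster_ids]


def common_motif_partition(dataset: Dataset, motif_len: int,
                           n_parts: int = 5, seed: int = 0) -> Dataset:
    """Assign cross-validation partitions with the shared-k-mer rule.

    Two peptides sharing any identical ungapped subsequence of length
    ``motif_len`` (closed transitively) always land in the same partition.
    """
    if n_parts < 2:
        raise ValueError("need at least 2 partitions")
    peptides = list(dataset.peptides)
    # cluster on unique sequences so duplicates co-locate by construction
    uniq = sorted(set(peptides))
    ids = cluster_by_shared_kmers(uniq, motif_len)
    parts = assign_clusters_to_partitions(ids, n_parts, seed)
    part_of = dict(zip(uniq, parts))
    out = dataset.records.copy()
    out["partition"] = [int(part_of[p]) for p in peptides]
    return Dataset(out, dataset.length_bounds, dataset.task)


def partition_union(datasets: list[Dataset], motif_len: int,
                    n_parts: int = 5, seed: int = 0) -> list[Dataset]:
    """Partition several datasets jointly so a peptide sequence always maps
    to the same fold across all of them."""
    all_peps = sorted({p for ds in datasets for p in ds.peptides})
    ids = cluster_by_shared_kmers(all_peps, motif_len)
    parts = assign_clusters_to_partitions(ids, n_parts, seed)
    part_of = dict(zip(all_peps, parts))
    out = []
    for ds in datasets:
        df = ds.records.copy()
        df["partition"] = [int(part_of[p]) for p in ds.peptides]
        out.append(Dataset(df, ds.length_bounds, ds.task))
    return out


# ---------------------------------------------------------------------------
# Cell-line panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellLinePanel:
    """A multi-allele label and its ordered candidate allele set."""

    cell_line: str
    alleles: tuple[str, ...]

    def __post_init__(self):
        if not self.alleles:
            raise ValueError(f"panel {self.cell_line} has no alleles")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"panel {self.cell_line} has duplicate alleles")


def read_panel_table(path) -> dict[str, CellLinePanel]:
    """Read ``cell_line<TAB>comma-separated-alleles`` lines."""
    panels: dict[str, CellLinePanel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 'cell_line<TAB>alleles'")
            name, alleles = parts
            panels[name] = CellLinePanel(
                name, tuple(a.strip() for a in alleles.split(",") if a.strip()))
    if not panels:
        raise ParseError(f"{path}: empty panel table")
    return panels


def write_panel_table(panels: dict[str, CellLinePanel], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(panels):
            fh.write(f"{name}\t{','.join(panels[name].alleles)}\n")


def validate_panels(panels: dict[str, CellLinePanel],
                    pseudo_table: dict) -> None:
    for panel in panels.values():
        for allele in panel.alleles:
            if allele not in pseudo_table:
                raise ParseError(
                    f"panel {panel.cell_line}: allele {allele} missing from "
                    f"pseudo-sequence table")
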