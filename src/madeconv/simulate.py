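"""Synthetic ground-truth worlds for end-to-end testing.

A *world* is a set of alleles with known position-specific scoring matrices
(PSSMs), pseudo-sequences constructed so that pseudo-sequence similarity
tracks motif similarity, cell-line panels with co-occurrence/exclusion
structure, and a random background proteome.  From a world one can draw
single-allele (SA) affinity and ligand datasets and multi-allele (MA)
ligand mixtures whose true restrictions are recorded as hidden ground
truth, which makes deconvolution accuracy directly measurable.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import (
    CellLinePanel,
    Dataset,
    Proteome,
    dedupe_sa_vs_ma,
    enrich_negatives,
    make_records,
    partition_union,
)
from .encoding import ALPHABET, AllelePseudoSequence, N_RESIDUES
from .metrics import pearson

_LOCI = "AABBCC"  # allele index -> locus letter (cycled)


@dataclass(frozen=True)
class FixtureSpec:
    """Layout and sizes of a synthetic world."""

    n_alleles: int = 6
    # index tuples into the allele list
    panel_layout: tuple[tuple[int, ...], ...] = (
        (0, 1, 2), (1, 3, 4), (2, 3, 5), (1, 4, 5))
    ma_only: tuple[int, ...] = (5,)
    low_abundance: tuple[tuple[int, float], ...] = ((4, 0.05),)
    distant_pseudo: tuple[int, ...] = ()
    max_motif_pcc: float = 0.2
    n_ma_per_panel: int = 400
    n_sa_el: int = 250
    n_sa_ba: int = 60
    # alleles with SA data only, present in no panel: they teach the
    # pan-specific pseudo-sequence -> motif mapping (the real SA compendia
    # cover many more alleles than any cell-line panel does)
    n_background_sa: int = 10
    n_sa_el_background: int = 150
    length_bounds: tuple[int, int] = (9, 9)
    length_dist: tuple[tuple[int, float], ...] = ((9, 1.0),)
    core_len: int = 9
    pseudo_len: int = 34
    ba_noise: float = 0.05
    anchor_positions: tuple[int, ...] = (1, 3, 6, 8)
    anchor_weight: float = 0.8
    anchor_second: float = 0.1
    proteome_sequences: int = 60
    proteome_length: int = 500
    n_partitions: int = 5
    motif_len: int = 8

    def __post_init__(self):
        if not any(len([p for p in self.panel_layout if i in p]) >= 2
                   for i in range(self.n_alleles)):
            raise ValueError("need an allele shared between >= 2 panels")
        counts = [sum(i in p for p in self.panel_layout)
                  for i in range(self.n_alleles)]
        if 1 not in counts and self.n_alleles > 2:
            raise ValueError("need an allele present in exactly one panel")


@dataclass
class GroundTruthAllele:
    name: str
    pseudo: AllelePseudoSequence
    pssm: np.ndarray  # (core_len, 20), row-stochastic
    locus: str


@dataclass
class World:
    spec: FixtureSpec
    alleles: dict[str, GroundTruthAllele]
    panels: dict[str, CellLinePanel]
    panel_weights: dict[str, dict[str, float]]
    proteome: Proteome
    seed: int

    @property
    def allele_names(self) -> list[str]:
        """Core (panel) alleles, in index order."""
        return [_allele_name(i) for i in range(self.spec.n_alleles)]

    @property
    def background_names(self) -> list[str]:
        n = self.spec.n_alleles
        return [_allele_name(n + i) for i in range(self.spec.n_background_sa)]

    @property
    def pseudo_table(self) -> dict[str, AllelePseudoSequence]:
        return {n: a.pseudo for n, a in self.alleles.items()}

    @property
    def locus_map(self) -> dict[str, str]:
        return {n: a.locus for n, a in self.alleles.items()}

    @property
    def sa_allele_names(self) -> list[str]:
        skip = {self.allele_names[i] for i in self.spec.ma_only}
        core = [n for n in self.allele_names if n not in skip]
        return core + self.background_names


def _allele_name(i: int) -> str:
    return f"HLX-{_LOCI[i % len(_LOCI)]}{i + 1:02d}"


def _sample_pssm(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    pssm = rng.dirichlet(np.full(N_RESIDUES, 5.0), size=spec.core_len)
    for p in spec.anchor_positions:
        main, second = rng.choice(N_RESIDUES, size=2, replace=False)
        row = np.full(N_RESIDUES,
                      (1.0 - spec.anchor_weight - spec.anchor_second)
                      / (N_RESIDUES - 2))
        row[main] = spec.anchor_weight
        row[second] = spec.anchor_second
        pssm[p] = row
    return pssm


def _pseudo_from_pssm(pssm: np.ndarray, spec: FixtureSpec,
                      background: str, distant: bool,
                      rng: np.random.Generator) -> str:
    if distant:
        return "".join(ALPHABET[i] for i in
                       rng.integers(0, N_RESIDUES, size=spec.pseudo_len))
    chars = list(background)
    # copy the motif-defining residue of each anchor into two fixed slots,
    # so pseudo-sequence distance tracks motif dissimilarity
    for k, p in enumerate(spec.anchor_positions):
        top = int(np.argmax(pssm[p]))
        chars[2 * k] = ALPHABET[top]
        chars[2 * k + 1] = ALPHABET[top]
    return "".join(chars)


def make_world(spec: FixtureSpec, seed: int) -> World:
    """Sample a world: PSSMs rejection-resampled until all pairwise motif
    correlations stay below ``spec.max_motif_pcc``, pseudo-sequences
    derived from the motifs, panels and a background proteome."""
    rng = np.random.default_rng([seed, 0x30BD])
    n_total = spec.n_alleles + spec.n_background_sa
    pssms: list[np.ndarray] = []
    for i in range(n_total):
        for attempt in range(500):
            cand = _sample_pssm(spec, rng)
            if all(abs(pearson(cand, other)) <= spec.max_motif_pcc
                   for other in pssms):
                pssms.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not reach motif separation {spec.max_motif_pcc}")
    background = "".join(ALPHABET[i] for i in
                         rng.integers(0, N_RESIDUES, size=spec.pseudo_len))
    alleles = {}
    for i, pssm in enumerate(pssms):
        name = _allele_name(i)
        residues = _pseudo_from_pssm(pssm, spec, background,
                                     i in spec.distant_pseudo, rng)
        alleles[name] = GroundTruthAllele(
            name=name, pseudo=AllelePseudoSequence(name, residues),
            pssm=pssm, locus=_LOCI[i % len(_LOCI)])
    names = [_allele_name(i) for i in range(n_total)]

    panels = {}
    weights = {}
    low = dict(spec.low_abundance)
    for j, idxs in enumerate(spec.panel_layout):
        cl = f"CL-{j + 1:02d}"
        members = tuple(names[i] for i in idxs)
        panels[cl] = CellLinePanel(cl, members)
        w = {}
        fixed = {names[i]: low[i] for i in idxs if i in low}
        rest = [names[i] for i in idxs if i not in low]
        remaining = 1.0 - sum(fixed.values())
        for n in members:
            w[n] = fixed.get(n, remaining / len(rest) if rest else 0.0)
        weights[cl] = w

    prot_rng = np.random.default_rng([seed, 0x9607])
    seqs = {}
    for i in range(spec.proteome_sequences):
        seqs[f"PROT{i + 1:04d}"] = "".join(
            ALPHABET[j] for j in
            prot_rng.integers(0, N_RESIDUES, size=spec.proteome_length))
    return World(spec=spec, alleles=alleles, panels=panels,
                 panel_weights=weights, proteome=Proteome(seqs), seed=seed)


# ---------------------------------------------------------------------------
# Peptide sampling
# ---------------------------------------------------------------------------

def _sample_core(pssm: np.ndarray, rng: np.random.Generator) -> str:
    return "".join(ALPHABET[rng.choice(N_RESIDUES, p=row)] for row in pssm)


def _realize_length(core: str, length: int,
                    rng: np.random.Generator) -> str:
    """Stretch or shrink a sampled core to the requested peptide length in
    a way the core-enumeration semantics can undo (contiguous interior
    insertions; single interior deletion for short peptides)."""
    k = len(core)
    if length == k:
        return core
    if length > k:
        ins = "".join(ALPHABET[i] for i in
                      rng.integers(0, N_RESIDUES, size=length - k))
        pos = int(rng.integers(1, k))
        return core[:pos] + ins + core[pos:]
    if length != k - 1:
        raise ValueError("can only shrink by one residue")
    pos = int(rng.integers(1, k - 1))
    return core[:pos] + core[pos + 1:]


def sample_el_positives(allele: GroundTruthAllele, n: int,
                        length_dist: dict[int, float],
                        rng: np.random.Generator) -> list[str]:
    """Eluted-ligand-like positives: PSSM-sampled cores realized at lengths
    drawn from ``length_dist``."""
    if n <= 0:
        raise ValueError("n must be positive")
    lengths = sorted(length_dist)
    probs = np.array([length_dist[l] for l in lengths], dtype=float)
    probs /= probs.sum()
    out = []
    for _ in range(n):
        L = int(rng.choice(lengths, p=probs))
        out.append(_realize_length(_sample_core(allele.pssm, rng), L, rng))
    return out


def pssm_log_score(peptide: str, pssm: np.ndarray) -> float:
    return float(sum(math.log(pssm[p, ALPHABET.index(ch)])
                     for p, ch in enumerate(peptide)))


def build_ma_dataset(world: World, cell_line: str, n: int,
                     rng: np.random.Generator) -> Dataset:
    """MA positives for one panel: each peptide drawn from a panel allele
    with probability equal to its abundance weight; the true source allele
    is recorded in a hidden ``true_allele`` column."""
    panel = world.panels[cell_line]
    weights = world.panel_weights[cell_line]
    names = list(panel.alleles)
    p = np.array([weights[a] for a in names])
    p /= p.sum()
    ld = dict(world.spec.length_dist)
    peptides, truth = [], []
    for _ in range(n):
        a = names[int(rng.choice(len(names), p=p))]
        peptides.append(sample_el_positives(world.alleles[a], 1, ld, rng)[0])
        truth.append(a)
    df = make_records(peptides, np.ones(n), cell_line, assay="EL",
                      origin="MA", true_allele=truth)
    return Dataset(df, world.spec.length_bounds, "classI")


def build_sa_datasets(world: World, rng: np.random.Generator,
                      leave_out: tuple[str, ...] = ()) -> tuple[Dataset, Dataset]:
    """SA (BA, EL) datasets for every allele with SA coverage.

    BA targets are a monotone logistic transform of the PSSM log-odds score
    with optional Gaussian noise; EL positives come from the PSSM.
    """
    spec = world.spec
    ld = dict(spec.length_dist)
    background = set(world.background_names)
    ba_parts, el_parts = [], []
    for name in world.sa_allele_names:
        if name in leave_out:
            continue
        allele = world.alleles[name]
        n_el = spec.n_sa_el_background if name in background else spec.n_sa_el
        if n_el > 0:
            peps = sample_el_positives(allele, n_el, ld, rng)
            el_parts.append(make_records(peps, np.ones(len(peps)), name,
                                         assay="EL", origin="SA"))
        if spec.n_sa_ba > 0:
            half = spec.n_sa_ba // 2
            peps = sample_el_positives(allele, half, {spec.core_len: 1.0}, rng)
            peps += world.proteome.sample_peptides(
                spec.core_len, spec.n_sa_ba - half, rng)
            e_self = sum((row * np.log(row)).sum() for row in allele.pssm)
            e_bg = sum(np.log(row).mean() for row in allele.pssm)
            mid, span = (e_self + e_bg) / 2.0, (e_self - e_bg) / 6.0
            targets = []
            for pep in peps:
                s = pssm_log_score(pep, allele.pssm)
                t = 1.0 / (1.0 + math.exp(-(s - mid) / span))
                if spec.ba_noise > 0:
                    t += rng.normal(0.0, spec.ba_noise)
                targets.append(float(np.clip(t, 0.0, 1.0)))
            ba_parts.append(make_records(peps, targets, name,
                                         assay="BA", origin="SA"))
    empty = make_records([], [], [], assay="BA", origin="SA")
    ba = Dataset(pd.concat(ba_parts, ignore_index=True) if ba_parts else empty,
                 spec.length_bounds, "classI")
    el = Dataset(pd.concat(el_parts, ignore_index=True) if el_parts else
                 make_records([], [], [], assay="EL", origin="SA"),
                 spec.length_bounds, "classI")
    return ba, el


def plant_epitope(antigen_len: int, epitope: str, seed: int,
                  name: str = "ANTIGEN") -> tuple[str, str, int]:
    """Embed an epitope in a random background protein.

    Returns (name, sequence, position).
    """
    if antigen_len < len(epitope):
        raise ValueError("antigen shorter than epitope")
    rng = np.random.default_rng([seed, 0xE417])
    bg = [ALPHABET[i] for i in rng.integers(0, N_RESIDUES, size=antigen_len)]
    pos = int(rng.integers(0, antigen_len - len(epitope) + 1))
    seq = "".join(bg[:pos]) + epitope + "".join(bg[pos + len(epitope):])
    return name, seq, pos


# ---------------------------------------------------------------------------
# Full training bundles
# ---------------------------------------------------------------------------

@dataclass
class TrainingBundle:
    sa: Dataset               # BA + EL single-allele records, partitioned
    ma: Dataset               # MA records (with hidden truth), partitioned
    world: World


def build_training_bundle(world: World, seed: int,
                          leave_out: tuple[str, ...] = ()) -> TrainingBundle:
    """Generate, deduplicate, negative-enrich and jointly partition the
    SA and MA training data of a world."""
    spec = world.spec
    rng = np.random.default_rng([seed, 0xDA7A])
    sa_ba, sa_el = build_sa_datasets(world, rng, leave_out=leave_out)
    ma_parts = [build_ma_dataset(world, cl, spec.n_ma_per_panel, rng)
                for cl in sorted(world.panels)]
    ma = Dataset(pd.concat([d.records for d in ma_parts], ignore_index=True),
                 spec.length_bounds, "classI")
    sa_el = dedupe_sa_vs_ma(sa_el, ma)
    if len(sa_el):
        sa_el = enrich_negatives(sa_el, world.proteome, seed=seed + 1)
    ma = enrich_negatives(ma, world.proteome, seed=seed + 2)
    sa = Dataset(pd.concat([sa_ba.records, sa_el.records], ignore_index=True),
                 spec.length_bounds, "classI")
    sa, ma = partition_union([sa, ma], spec.motif_len,
                             n_parts=spec.n_partitions, seed=seed + 3)
    return TrainingBundle(sa=sa, ma=ma, world=world)


# ---------------------------------------------------------------------------
# Canned specs used by the test-suite and acceptance runs
# ---------------------------------------------------------------------------

def default_world_spec() -> FixtureSpec:
    """The default 6-allele / 4-panel world: one MA-only allele, one
    low-abundance allele, well-separated motifs."""
    return FixtureSpec()


def varied_length_spec() -> FixtureSpec:
    """A smaller world with a class-I-like 8-11 length distribution, for
    exercising the insertion/deletion core machinery end to end."""
    return FixtureSpec(
        n_alleles=3,
        panel_layout=((0, 1), (0, 2)),
        ma_only=(0,),
        low_abundance=(),
        n_ma_per_panel=150,
        n_sa_el=120,
        n_sa_ba=40,
        n_background_sa=4,
        n_sa_el_background=80,
        length_bounds=(8, 11),
        length_dist=((8, 0.15), (9, 0.60), (10, 0.15), (11, 0.10)),
    )


def cooccurrence_spec() -> FixtureSpec:
    """Two panels sharing exactly one (MA-only) allele; 9mers only, small."""
    return FixtureSpec(
        n_alleles=3,
        panel_layout=((0, 1), (0, 2)),
        ma_only=(0,),
        low_abundance=(),
        n_ma_per_panel=200,
        n_sa_el=120,
        n_sa_ba=40,
        n_background_sa=8,
        n_sa_el_background=100,
        max_motif_pcc=0.15,
    )


def depressed_allele_spec() -> FixtureSpec:
    """Like the co-occurrence fixture, but the shared MA-only allele also
    has a pseudo-sequence far from everything in the SA data, so its raw
    pre-training scores are systematically depressed."""
    return FixtureSpec(
        n_alleles=3,
        panel_layout=((0, 1), (0, 2)),
        ma_only=(0,),
        low_abundance=(),
        distant_pseudo=(0,),
        n_ma_per_panel=200,
        n_sa_el=120,
        n_sa_ba=40,
        n_background_sa=8,
        n_sa_el_background=100,
        max_motif_pcc=0.15,
    )


def write_fixture_dir(bundle: TrainingBundle, outdir) -> None:
    """Emit the full fixture directory as plain-text files."""
    import os

    import yaml

    from .data import write_panel_table, write_peptide_table
    from .encoding import write_pseudo_table

    os.makedirs(outdir, exist_ok=True)
    world = bundle.world
    sa = bundle.sa.records
    ba = Dataset(sa[sa["assay"] == "BA"].reset_index(drop=True),
                 bundle.sa.length_bounds)
    el = Dataset(sa[sa["assay"] == "EL"].reset_index(drop=True),
                 bundle.sa.length_bounds)
    write_peptide_table(ba, os.path.join(outdir, "sa_ba.tsv"))
    write_peptide_table(el, os.path.join(outdir, "sa_el.tsv"))
    write_peptide_table(bundle.ma, os.path.join(outdir, "ma_el.tsv"))
    bundle.ma.records.to_csv(os.path.join(outdir, "ma_truth.tsv"),
                             sep="\t", index=False)
    write_panel_table(world.panels, os.path.join(outdir, "panels.tsv"))
    write_pseudo_table(world.pseudo_table,
                       os.path.join(outdir, "pseudosequences.dat"))
    world.proteome.to_fasta(os.path.join(outdir, "proteome.fasta"))
    spec_doc = asdict(world.spec)
    spec_doc["seed"] = world.seed
    with open(os.path.join(outdir, "world.yaml"), "w") as fh:
        yaml.safe_dump(spec_doc, fh)
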