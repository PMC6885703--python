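# madeconv

Semi-supervised deconvolution of multi-allele (MA) MHC eluted-ligand data
with a pan-specific binding-core neural network.

Mass-spectrometry immunopeptidomes are poly-specific: a cell line expresses
several MHC molecules, so each eluted ligand could have been presented by
any of them. `madeconv` resolves the restriction of every ligand while
training a predictor:

1. **Pre-training (burn-in)** — a one-hidden-layer network with two output
   neurons (binding affinity + eluted-ligand likelihood) is trained on
   single-allele (SA) data only.  Peptides are represented by a max-scored
   9-residue binding core; the allele by a fixed-length pseudo-sequence of
   groove contact residues, making the model pan-specific.
2. **Annotation** — after burn-in, every positive MA ligand is scored
   against all alleles of its cell line's panel.  Raw scores are converted
   to z-scores against the allele's score distribution on random natural
   peptides (trimmed-normal fit, refreshed every iteration, blended toward
   across-allele averages on a sigmoidal schedule), and the argmax allele
   is assigned.  Negative MA records are tagged with a random panel allele.
3. **Retraining** — SA and annotated MA data are merged (respecting the
   cross-validation partitioning) and training continues, re-annotating at
   every iteration.  Co-occurrence/exclusion structure across panels pulls
   shared motifs onto shared alleles.

The package also ships the evaluation stack (AUC, AUC0.1, Frank epitope
ranking, positive predictive values, motif construction and comparison,
locus peptidome shares) and a synthetic ground-truth world generator so the
whole pipeline is testable offline.

## Layout

| module                 | contents                                                       |
|------------------------|----------------------------------------------------------------|
| `madeconv.encoding`    | alphabet, BLOSUM input encoding, binding-core enumeration, pseudo-sequences, allele distances |
| `madeconv.data`        | peptide table IO, BA target transform, random-natural negative enrichment, SA/MA dedup, common-motif cross-validation partitioning |
| `madeconv.network`     | the two-output network, per-example SGD with argmax-core backprop, fold training, ensembles, serialization |
| `madeconv.engine`      | score rescaling, MA annotation, the full semi-supervised loop  |
| `madeconv.metrics`     | AUC/AUC0.1, Frank, PPV, motifs, locus shares                   |
| `madeconv.simulate`    | synthetic alleles/panels/proteomes with hidden ground truth    |
| `madeconv.cli`         | `madeconv` command-line entry point                            |

## CLI

```bash
madeconv simulate --out fixture/ --seed 1 --preset default
madeconv train    --config config.yaml --out run/
madeconv annotate --model run/model.json --ma fixture/ma_el.tsv \
                  --panels fixture/panels.tsv --proteome fixture/proteome.fasta \
                  --out annotation.tsv
madeconv predict  --model run/model.json --peptides peps.tsv \
                  --allele HLX-A01 --out scores.tsv
madeconv evaluate --run run/ --out metrics/
madeconv motif    --model run/model.json --allele HLX-A01 \
                  --proteome fixture/proteome.fasta --out motif.tsv
```

`train` reads a YAML config with a `paths:` block (SA BA/EL, MA EL, panel
table, pseudo-sequence table, proteome FASTA) and a `train:` block of
hyper-parameters; see `tests/test_cli.py` for a worked example.  Run
directories are versioned, never overwritten, and contain the model, the
final cross-validated annotation, per-iteration history and out-of-fold
predictions.

## File formats

* peptide tables: `peptide<TAB>target<TAB>label` (TSV, no header)
* panels: `cell_line<TAB>comma-separated allele names`
* pseudo-sequences: `ALLELE_NAME PSEUDOSEQ` (whitespace separated)
* proteomes/antigens: FASTA; models: versioned JSON
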