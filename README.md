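# attnsol

Protein solubility prediction from sequence alone, with a built-in
explanation of *which residues* drive the prediction.

The model embeds each residue (shared 21 x 20 embedding), runs two
parallel 2-layer bidirectional GRU subnetworks over the sequence — a
*prediction* network P producing a per-residue solubility contribution
`p_i` (LeakyReLU) and an *attention* network A producing softmax
weights `a_i` that sum to one — and scores the chain as
`sigmoid(sum_i a_i * p_i)`. The products `a_i * p_i` form a per-residue
solubility profile that decomposes the score exactly, so the same
25,462-parameter model that classifies a sequence also localizes the
signal. On top of the classifier the package builds in-silico
mutagenesis (exhaustive single and tandem-pair substitution scans,
epistasis/synergy maps, structural-distance correlation), truncation
ablation experiments, and a synthetic-data generator with a planted
termini-localized signal so the whole pipeline is testable offline.

Everything is NumPy: the forward pass, backpropagation through time,
and the Adam optimizer are implemented in the package; no deep-learning
framework is required. See `docs/methods.md` for the full methods note.

## Worked example (CLI)

All numbers below are actual output of the commands shown (they are
deterministic given the seeds; the demo trains 15 epochs on 300
sequences in about a minute on one CPU).

```console
$ attnsol count-params
25462

$ attnsol simulate --n 300 --min-length 50 --max-length 120 --data-seed 7 --out-prefix demo
wrote demo.fasta and demo.labels.tsv

$ attnsol train --fasta demo.fasta --labels demo.labels.tsv \
      --checkpoint model.npz --epochs 15 --batch-size 64
final epoch loss 0.6261; checkpoint model.npz

$ attnsol predict --fasta demo.fasta --checkpoint model.npz --out scores.tsv
$ head -3 scores.tsv
id	score
syn00000	0.570592
syn00001	0.933916

$ attnsol metrics --scores scores.tsv --labels demo.labels.tsv --out metrics.json
SEN 52.4  SPE 85.8  PRE 77.6  ACC 69.7  BAC 69.1  AUC 74.8  AUPRC 78.3  MCC 0.41
```

(Those metrics are on the training sequences themselves — a smoke test,
not an evaluation; the held-out benchmark is below.)

The label-generating rule of the simulator lives in the terminal 20% of
each chain, and the model finds it. Ablating the termini destroys the
signal while removing the central 20th–80th percentile span does not:

```console
$ attnsol ablate --fasta demo.fasta --labels demo.labels.tsv \
      --checkpoint model.npz --mode termini --out abl_termini.json
termini: full AUC 0.748 -> ablated AUC 0.528

$ attnsol ablate --fasta demo.fasta --labels demo.labels.tsv \
      --checkpoint model.npz --mode central --out abl_central.json
central: full AUC 0.748 -> ablated AUC 0.775
```

The attention weights show the same thing positionally — after even
this short training run the first fifth of the chain carries roughly
ten times the per-residue attention of the central bins:

```console
$ attnsol profile --fasta demo.fasta --checkpoint model.npz \
      --out profiles.tsv --summary-bins 5
$ cut -f1,2,4 profiles.tsv.summary.tsv
bin_lo	bin_hi	attention_mean
0.0000	0.2000	4.217357e-02
0.2000	0.4000	4.596923e-03
0.4000	0.6000	4.039631e-03
0.6000	0.8000	3.863880e-03
0.8000	1.0000	4.246112e-03
```

Mutational scanning works on any checkpoint: `attnsol scan-single`
writes the full L x 20 substitution-effect table, `attnsol scan-pairs`
streams the exhaustive tandem-pair scan (2,101,200 pairs for a
103-residue protein), `attnsol synergy` aggregates it to a mean-epistasis
position map and separation profile, and `attnsol distances` +
`attnsol correlate` relate that profile to C-beta distances from a PDB
structure. `attnsol --help` lists every command.

## The held-out benchmark

The full study condition — 2,000 training and 500 held-out sequences
from the planted-termini rule (dataset seed 7), 50 epochs, batch 256,
lr 0.01, Adam, L2 1e-6 — trains in 6–9 minutes on one CPU and
reaches (deterministically, model and shuffling seed 0):

- held-out AUC **0.862** (Bayes-optimal ranking on this test set: 0.973),
- mean attention mass in the terminal 20% of positions **0.882**
  (uniform attention would give 0.4),
- termini-ablated AUC **0.512** (signal destroyed, chance is 0.5),
- central-ablated AUC **0.912** (signal intact).

Reproduce it, along with every other headline quantity (parameter
count, pair-enumeration counts, decomposition/padding error bounds,
wildtype-null bounds, metric-oracle agreement), with:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The test suite (unit, property-based, and one acceptance test per
criterion, including the full benchmark above) runs with:

```bash
python -m pytest -q tests/
```

## Library use

```python
from attnsol.model import ModelConfig, predict
from attnsol.synthetic_data import generate_dataset
from attnsol.training import TrainConfig, train

records = generate_dataset(2500, seed=7)
params, history = train(records[:2000], ModelConfig(seed=0),
                        TrainConfig(batch_size=256, epochs=50, seed=0))
for out in predict(params, records[2000:2003]):
    print(out.id, round(out.score, 3), out.profile.sum())  # profile sums to the logit
```

Modules: `sequence_io` (FASTA/TSV, encoding, padding), `model`
(architecture, forward, checkpoints), `training` (BCE + Adam),
`profiles` (solubility profiles, positional summaries, propensity-scale
correlation), `truncation_eval` (metrics, truncation ablations),
`mutagenesis` (substitution scans, synergy, structure correlation),
`synthetic_data` (planted-rule generator), `cli`.
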