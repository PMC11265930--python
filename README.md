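# latchseq

Sequence analysis of extractive foraging at multi-latch puzzle boxes.

Field studies of animal innovation increasingly use multi-compartment
puzzle boxes whose doors can be opened by several different latch
mechanisms, with visiting individuals identified passively by RFID. The
resulting data are event logs — detections, door openings and re-baiting
events per site and night — from which the questions of interest are
behavioural: who solved the task, which solutions do individuals prefer,
how *individual* are their solving techniques, and how does the social
context (foraging alone versus under competition) shape them.

`latchseq` is a tested, reusable pipeline for that analysis, aimed at
behavioural ecologists working with categorical action sequences. It
covers:

* **event model** — parsing/validating event logs and rosters,
  segmenting visits into trials (a new trial after ≥ 1 min absence),
  classifying solvers (≥ 3 doors of one latch type; ≥ 2 latch types =
  flexible), tracking box state across re-baits, and labelling each
  trial *unrestricted* (first solver at an unopened box, never joined)
  or *competitive*;
* **sequence metrics** — for a latch sequence *x* of length *n* over
  the alphabet *A* = {H, R, V, S}: longitudinal entropy
  *h* = −Σ πᵢ ln πᵢ, transition count *q*, and the complexity index

      C(x) = sqrt( (q / (n−1)) · (h / ln|A|) )  ∈ [0, 1],

  plus optimal-matching (OM) edit distances with indel cost 1 and
  transition-rate substitution costs SC(i,j) = 2 − p(i→j) − p(j→i),
  normalised by the longer sequence length, partitioned into intra- and
  inter-individual comparisons per social condition;
* **inference** — χ² goodness-of-fit of latch preferences against
  uniform use, Mann–Whitney U comparisons of dissimilarity scores
  (exact for small tie-free samples), and binomial GLMs of solving
  success competed by forward stepwise selection with AICc,
  likelihood-ratio tests and Akaike weights;
* **synthetic data** — a seeded generator of event logs with known
  latent structure (Dirichlet latch preferences, sticky Markov
  switching, competition sharpening, work-time learning curves) so the
  whole pipeline is testable end to end without field data.

## Worked example

```python
from latchseq import (LatchSequence, complexity_index, estimate_transition_rates,
                      trate_costs, om_distance, normalize_distance, chisq_uniform_gof)

trial1 = LatchSequence.from_string("SSHVSH")
trial2 = LatchSequence.from_string("SHVSVH")
c = complexity_index(trial1)
print(f"entropy h = {c.h:.4f} nats, transitions q = {c.q}, complexity C = {c.C:.4f}")

sc = trate_costs(estimate_transition_rates([trial1, trial2]))
d = om_distance(trial1, trial2, sc)
print(f"OM distance = {d:.4f}, normalized = {normalize_distance(d, 6, 6):.4f}")

res = chisq_uniform_gof([21, 11, 3, 0])
print(f"chi2 = {res.statistic:.3f}, df = {res.df}, p = {res.p_value:.2e}")
```

prints

```
entropy h = 1.0114 nats, transitions q = 4, complexity C = 0.7640
OM distance = 2.0000, normalized = 0.3333
chi2 = 30.257, df = 3, p = 1.22e-06
```

The first trial uses three latch types with four switches in six
openings, giving a complexity of 0.76 on the 0–1 scale (0 = one latch
only, 1 = equal use of all four with a switch at every opening). The
two trials are two substitutions apart under the transition-rate costs,
i.e. 0.33 per opening of the longer sequence. The χ² line tests
first-opened latch counts (21, 11, 3, 0) against uniform use across the
four latches — the swivel latch is strongly over-represented.

## Command line

```bash
latchseq simulate --seed 3 --out data/        # events.csv, individuals.csv, truth.json
latchseq run-all --in data/ --out results/ --seed 3
```

`run-all` writes `trials.csv`, `sequences.csv`, `complexity.csv`,
`distances.csv`, `doors.csv`, `stats_report.json` and a digest
`summary.txt`, which for the command above begins:

```
latchseq pipeline summary
config_hash=7117a9a752104367 seed=3

individuals tested: 31  trials: 650  events: 2182
solvers: 5 (0.16 of tested), flexible: 5

latch preference (final trials per solver):
  first opened: {'H': 3, 'R': 1, 'V': 8, 'S': 13}  chi2=13.880 p=3.07e-03
```

Each stage (`segment`, `classify`, `sequences`, `complexity`,
`distances`, `stats`, `report`) is also available as its own
subcommand; every stage is a pure function of the inputs, the config
and the seed, and reports are stamped with a config hash.

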