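# gtoscreen

Wrapper-based feature selection and hyperparameter search built around the
**Artificial Gorilla Troops Optimizer (GTO)**, aimed at two clinical
machine-learning settings:

1. **Tabular screening data** (AQ-10-style autism screening questionnaires:
   ten binary items A1–A10 plus demographics): GTO searches over keep/drop
   feature masks, scoring each candidate subset by the grid-searched,
   stratified 5-fold cross-validated accuracy of a tree or boosting
   classifier (decision tree, extra tree, LightGBM).
2. **Two-class image data** (e.g. facial-image screening sets): GTO searches
   a 15-cell hyperparameter space (loss, batch size, dropout, transfer-learn
   ratio, optimizer, scaler, and eight data-augmentation settings) for an
   image classifier trained through a pluggable trainer contract.

Both dataset kinds can be emulated by built-in deterministic generators, so
everything here runs at desk scale with no downloads.

## The optimizer

GTO is a population metaheuristic. Each of the `N` candidate solutions
`X ∈ [LB, UB]^D` moves each iteration `t = 1..T` through:

**Exploration** — one of three mechanisms per member:

```
X' = LB + r1·(UB − LB)                              migration (prob. p)
X' = L·H + (r2 − C)·Xr,   H = Z·X, Z ~ U(−C, C)     follow a random peer
X' = X − L·(L·(X − Xr) + r3·(X − Xr))               move to a known position
```

**Exploitation** — follow the silverback (the best member) when `C ≥ w`,
otherwise compete around it:

```
X' = L·M·(X − Xsb) + X           follow,  M = (|mean(pop)|^g)^(1/g), g = 2^L
X' = Xsb − (Xsb·Q − X·Q)·A       compete, Q = 2r−1, A = β·E
```

with `C = (cos(2r4)+1)·(1 − t/T)` and `L = C·l`, `l ~ U(−1,1)`. Candidates
are clipped to the box and accepted greedily (strictly better only), so the
best fitness history is non-increasing. Defaults: `N = 10`, `T = 25`,
`p = 0.03`, `β = 3`, `w = 0.8`.

**Decoding.** For discrete hyperparameter cells the value `v ∈ [0,1]` maps to
a 1-based option index `⌈v·n⌉` (e.g. `v = 0.75` over the 12 batch sizes
{4, 8, …, 48} → index 9 → batch 36); continuous cells interpolate linearly.
For feature masks, column *i* is kept iff `cell_i ≥ 0.5` (an all-drop vector
falls back to keeping the argmax cell).

Reports carry the full confusion-count metric suite: accuracy, balanced
accuracy, precision, specificity, recall/sensitivity, F1, Dice, overlap
index, IoU, rank-based AUC, Youden index (`specificity + sensitivity − 1`)
and cosine similarity.

## Worked example

```python
from gtoscreen import (ScreeningGenSpec, generate_screening_table,
                       FSProblem, GTOParams, run_framework)
from gtoscreen.cli_io import report_text_table

table = generate_screening_table(ScreeningGenSpec(n=1100, missing_rate=0.03, seed=42))
problem = FSProblem(table=table, model_kind="DT", seed=42)
report = run_framework(problem, GTOParams(Nmax=10, Tmax=25, seed=42))
print(report_text_table(report))
```

prints

```
Problem	feature-selection
Grid Winner	{'criterion': 'gini', 'splitter': 'best'}
Scaling Technique	Standardization
Encoded Solution	00000000000000000100
No of Ones	1
Elapsed time (ms)	5,242
TP	194
TN	906
FP	0
FN	0
Accuracy	100 %
Balanced Accuracy	100 %
...
Youden Index	100 %
```

The generated table labels a row YES exactly when the ten item scores sum to
at least 7, and carries that sum in its `result` column; the optimizer
discovers that the single `result` column suffices (`Encoded Solution` has
one `1`, at that column) and the refit decision tree classifies all 1,100
rows perfectly out of fold — TP + TN = 1,100, every metric 100 %.

The same flow is available from the shell:

```bash
gtoscreen gen-data --kind table --n 1100 --seed 42 --out screening.csv
gtoscreen optimize-fs --data screening.csv --model DT --seed 42 --out runs/fs
gtoscreen gen-data --kind images --n-per-class 50 --seed 6 --out imgs/
gtoscreen optimize-tl --data imgs/ --nmax 4 --tmax 3 --seed 6 --out runs/tl
```

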