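# mitopop

Single-locus population genetics for haploid mtDNA markers (e.g. a COI
barcode fragment): haplotype inference and count tables, haplotype and
nucleotide diversity, AMOVA and pairwise Φ<sub>ST</sub> with permutation
tests, Tajima's *D* and Fu's *F*<sub>S</sub> neutrality tests with
coalescent-simulation p-values, mismatch-distribution fitting under the
sudden-expansion model (with expansion-time dating via τ = 2*u*t),
median-joining haplotype networks, neighbor-joining trees with bootstrap
support, and a coalescent simulator for generating test data.

The package is aimed at phylogeography studies of the common
marine-invertebrate kind: several localities, tens of individuals each, one
non-recombining mitochondrial fragment, and the standard question — how much
diversity is there, is the species subdivided, and has it recently expanded?
It reimplements, as one tested library, the workflow usually spread across
DnaSP, Arlequin and NETWORK.

## The statistics

For haplotype counts *c*₁…*c*ₖ (n = Σ*c*ᵢ), haplotype diversity is Nei's
unbiased estimator

    h = n(1 − Σ (cᵢ/n)²) / (n − 1).

Nucleotide diversity π is the mean per-site difference fraction over all
sequence pairs (pairwise masking of gaps/ambiguities); k̂ is the mean raw
pairwise difference count. AMOVA partitions squared pairwise differences
into among- (Va) and within-population (Vb) variance components with
Φ<sub>ST</sub> = Va/(Va+Vb), tested by permuting individuals among
populations. Tajima's D contrasts k̂ with Watterson's S/a₁; Fu's
*F*<sub>S</sub> = ln(S′/(1−S′)) with S′ = P(K ≥ k<sub>obs</sub>) under the
Ewens sampling formula. The mismatch distribution is compared with the
Rogers–Harpending sudden-expansion model F(τ, θ₀, θ₁) fitted by least
squares, with parametric-bootstrap p-values for SSD and Harpending's
raggedness, and τ converted to years through τ = 2*u*t. Networks follow
Bandelt's median-joining construction over a minimum-spanning-network
backbone. See `docs/methods.md` for assumptions and numerical details.

## Worked example

The package ships a deterministic fixture reconstructing a six-locality,
390-individual haplotype count table (65 barnacles per locality, 84
haplotypes over a 683 bp COI fragment):

```bash
mitopop simulate --mode table1 --out data
mitopop haplotypes --fasta data/alignment.fasta --popmap data/popmap.tsv --out results
mitopop diversity  --fasta data/alignment.fasta --popmap data/popmap.tsv --out results
```

prints

```
390 sequences x 683 sites -> data
84 haplotypes from 390 sequences; 59 private, 25 shared; dominant H2: 224 (57.44%) in 6 populations
               n  n_haplotypes      h       pi  k_hat
population
ND          65.0          32.0  0.789  0.00157  1.073
QZ          65.0          19.0  0.688  0.00128  0.874
XM          65.0          12.0  0.475  0.00080  0.544
ZZ          65.0          17.0  0.668  0.00123  0.838
FZ          65.0          20.0  0.584  0.00103  0.703
PT          65.0          27.0  0.756  0.00147  1.005
mean         NaN           NaN  0.660  0.00123  0.840
```

84 haplotypes were found, 59 of them private to one locality; the dominant
haplotype accounts for 57.44% of individuals and occurs everywhere — the
classic signature of a recent expansion with high gene flow. The `h` column
is recomputed from the counts alone (so it reproduces the published values
exactly); `pi` and `k_hat` depend on the fixture's synthetic stand-in
sequences and are only order-of-magnitude realistic.

`mitopop all` runs the complete workflow (diversity, AMOVA, pairwise
Φ<sub>ST</sub>, neutrality tests, mismatch fits with dating, network, NJ
tree) into one output directory; every stochastic stage derives its seed
from the single `--seed` flag, so re-runs are byte-identical.

The same functionality is available as a library:

```python
import mitopop as mp

ds = mp.simulate_fujian_like(seed=1)          # 6 demes x 65, recent expansion
table = mp.collapse_haplotypes(ds.alignment)
print(mp.summarize_diversity(table, ds.alignment))
print(mp.neutrality_tests(ds.alignment, n_sims=1000, seed=1))
```

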