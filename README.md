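# bbdisp

Base-level beta-binomial modeling of RNA-seq read-start counts, for
comparing two samples (or two groups of replicates) at single-nucleotide
resolution.

RNA-seq coverage is wildly non-uniform along a gene — random-hexamer
priming alone can change per-base read starts 100-fold — so gene-level
count models leave information on the table and per-base Poisson models
are badly underdispersed.  `bbdisp` instead models, at every base j of
gene i, the *split* of read starts between two samples:

    n_ij | n_ij + m_ij  ~  BetaBinomial(t_ij; p_i, theta_ij)

where p_i is the gene's true proportion (the quantity of biological
interest) and theta_ij the per-base overdispersion rate.  The rate is not
a constant: it follows a log-linear law in sequencing depth and the local
sequence flanking the read start,

    log theta_ij = log D + Σ_k Σ_{h∈{A,T,C}} β_kh I(b_ijk = h) + γ log t_ij

(K = 80 window, reference base G, depth exponent γ < 0, pair-specific
scale D).  γ and β_kh are trained once on replicate pairs via a
method-of-moments estimate of theta regressed by least squares; each test
pair then gets its own D and per-gene p̂_i by iterative likelihood
maximization, and genes are tested with a likelihood-ratio χ² (1 df per
sample pair, summed across pairs).  The package also ships the full
model-comparison machinery (nested χ² tests, AIC under two
parameter-counting conventions, repeated 5-fold cross-validated R²),
diagnostics (theta vs. depth, theta vs. distance to gene end, coefficient
profiles around the read start), and a ground-truth simulator.

Who it is for: people analyzing deep two-condition comparisons with
technical replicates or spike-ins (cell-line stimulation experiments,
reference-sample benchmarks), and people studying RNA-seq bias and
dispersion themselves.

## Worked example

Train the depth-dependent model on four simulated replicates, then test a
fresh sample pair containing one truly changed gene:

```python
import bbdisp as bb

cfg = bb.SimulationConfig(seed=4, G=100, gene_length=300, median_depth=80.0,
                          depth_sigma=1.0, variant="primer_free", D=1.0,
                          gamma=-0.8, K=8)
sim = bb.simulate_replicates(cfg, n_samples=4)
trained = bb.train(sim.counts, sim.genes, sim.sample_ids,
                   bb.DesignSpec(K=8), variant="primer_free")
m = trained.model
print(f"gamma_hat = {m.gamma:.3f}   logD_hat = {m.logD:.3f}   "
      f"in-sample R2 = {m.r_squared:.3f}   positions = {m.n_obs}")

pair = bb.simulate_pair(bb.SimulationConfig(
    seed=5, G=100, gene_length=300, median_depth=80.0, depth_sigma=1.0,
    variant="primer_free", D=1.0, gamma=-0.8, de_fraction=0.01, de_p=0.8, K=8))
state = bb.fit_test_pair(pair.paired, m, bb.PipelineConfig(model="bb_D_g", K=8),
                         mode="comparison")
res = bb.lrt_genes([state])
res["qvalue"] = bb.adjust_pvalues(res["pvalue"])
print(f"pair D_hat = {state.D:.3f}")
print(res.nsmallest(3, "pvalue")[["gene_id", "p_hat", "chi2", "df",
                                  "pvalue", "qvalue"]].to_string(index=False))
```

Output:

```
gamma_hat = -0.830   logD_hat = -0.127   in-sample R2 = 0.298   positions = 24241
pair D_hat = 1.150
gene_id    p_hat        chi2  df   pvalue   qvalue
  g0068 0.796787 4398.287240   1 0.000000 0.000000
  g0045 0.488713    8.384984   1 0.003783 0.189167
  g0069 0.490396    6.534822   1 0.010578 0.334118
```

The trained depth exponent (−0.83) is close to the generating −0.8; the
pair's dispersion scale D̂ = 1.15 absorbs the library effect.  The one
truly changed gene (g0068, generated at p = 0.8 against a neutral 0.5) is
recovered with p̂ = 0.797 and an overwhelming χ²; the runner-up genes are
null and do not survive BH adjustment.

The same flow is available from the shell:

```
bbdisp simulate --config sim.yaml --n-samples 4 --out sim/
bbdisp train    --counts sim/counts.tsv --fasta sim/genes.fa \
                --samples sim/samples.tsv --variant primer_free --out model/
bbdisp test     --counts sim/counts.tsv --samples sim/samples.tsv \
                --model model/model_antisense.tsv --group-a x --group-b y \
                --out de/
bbdisp compare  --counts sim/counts.tsv --fasta sim/genes.fa \
                --samples sim/samples.tsv --out cmp/
bbdisp profile  --kind depth --observations model/theta_observations.tsv \
                --out prof/
```

Every command writes a JSON manifest (parameters, seed, input checksums)
next to its outputs.

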