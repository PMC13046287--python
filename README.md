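# telenb

Model selection and transcriptional-burst inference for single-cell RNA-seq
transcript counts: telegraph (Beta-Poisson) vs negative binomial vs Poisson,
with explicit modelling of transcript-capture technical noise.

## Why

The negative binomial is the near-universal fit for UMI count distributions,
and a good NB fit is routinely read as evidence of transcriptional bursting
(rare activation, `sigma_on << sigma_off`), with the two NB parameters
reported as burst frequency and burst size.  Neither inference is safe.  The
steady-state telegraph model — a gene switching between an active state
(transcribing at rate `rho`) and an inactive one with rates `sigma_on`,
`sigma_off`, all normalized by mRNA degradation — has the Beta-Poisson law

    n ~ Poisson(rho x),  x ~ Beta(sigma_on, sigma_off),

and converges to its moment-matched "effective NB"

    r_e = sigma_on (N+1) / sigma_off,
    p_e = N(N+1) / (N(N+1) + rho sigma_off),   N = sigma_on + sigma_off,

at rate `O(1/N)` as the switching speed `N` grows — bursting or not.  So NB
fits are excellent in a broad crescent of the `(N_sigma, f_on)` plane
(`f_on = sigma_on/N`), and inside that region the burst parameters implied
by the NB, `beta_f = r_e` and `beta_s = 1/p_e - 1`, differ from the true
`sigma_on` and `rho/sigma_off` by closed-form relative errors that are
typically large.  Capture noise — each transcript observed with per-cell
probability `pcap` — shifts the picture further: fixed `pcap` merely
rescales `rho`, but cell-to-cell variability in `pcap` (Beta-distributed
here) inflates the Fano factor and systematically converts Poisson-best
genes into NB-best genes.

`telenb` quantifies all of this for people analysing or simulating scRNA-seq
counts: exact pmfs for all three models with and without capture noise, a
fast model-selection criterion (aeBIC) that assigns a unique best model to
every parameter point, phase-diagram scanners, burst-parameter estimators
with their error formulas, a gene-pair ranking protocol, a marginalized-MLE
per-gene fitting pipeline for count matrices, and a fully ground-truthed
synthetic genome generator.

The selection criterion is the approximate expected BIC,

    aeBIC(M, n_c) = |M| ln n_c + 2 n_c eps_c(M_fit, G),

with `eps_c` the cross entropy between the fitted candidate and the
ground-truth pmf `G`; it upper-bounds and closely tracks the BIC averaged
over repeated samples of `n_c` cells while requiring a single fit.

## Worked example

```python
from telenb import (TelegraphParams, telegraph_pmf, effective_nb_params,
                    nb_pmf, kl_divergence, burst_relative_errors,
                    PhaseGrid, phase_scan)

# a fast-switching gene, active 30% of the time: NOT bursty
gene = TelegraphParams.from_fon_nsigma(rho=15.0, f_on=0.3, n_sigma=30.0)
print(f"sigma_on = {gene.sigma_on:.1f}, sigma_off = {gene.sigma_off:.1f}")

nb = effective_nb_params(gene)
print(f"effective NB: r_e = {nb.r:.2f}, p_e = {nb.p:.3f}")

truth = telegraph_pmf(gene)
approx = nb_pmf(nb, n_max=truth.n_max)
print(f"KL(NB_eff || telegraph) = {kl_divergence(approx, truth):.2e}")

re_size, re_freq = burst_relative_errors(gene.f_on, gene.n_sigma)
print(f"burst-parameter relative errors: size {re_size:.2f}, frequency {re_freq:.2f}")

diagram = phase_scan(PhaseGrid(n_nsigma=52, n_fon=25), rho=15.0, nc=100)
print({k: round(v, 1) for k, v in diagram.fractions.items()})
```

prints

```
sigma_on = 9.0, sigma_off = 21.0
effective NB: r_e = 13.29, p_e = 0.747
KL(NB_eff || telegraph) = 7.30e-05
burst-parameter relative errors: size 0.53, frequency 0.48
{'telegraph': 32.8, 'nb': 20.2, 'poisson': 46.9}
```

Read: this gene is active 30% of the time and switches ~30 times per mRNA
lifetime — nothing like bursting — yet the effective NB is essentially
indistinguishable from its true distribution (KL ~ 7e-5, invisible at any
realistic sample size).  Reading burst parameters off that NB fit would be
off by ~50% in both size and frequency.  Across the whole
`(N_sigma, f_on)` plane at 100 cells, the NB is the aeBIC-optimal model on
about 20% of parameter space, between a telegraph region (slow switching)
and a Poisson region (fast switching).

The CLI mirrors the library: `telenb simulate | phase-diagram | fit | rank
| qc` (see `telenb --help`).  Count matrices are MatrixMarket (`.mtx` plus
gene/cell label TSVs) or dense CSV.

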