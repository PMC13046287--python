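# Methods

## The models

`telenb` works with three steady-state models of a single gene's transcript
count in a cell, all with rates normalized by the mRNA degradation rate:

- **Telegraph (Beta-Poisson).** The gene switches between an inactive and an
  active state with rates `sigma_on` (activation) and `sigma_off`
  (inactivation) and transcribes at rate `rho` only while active.  At steady
  state the count is distributed as `n ~ Poisson(rho x)` with
  `x ~ Beta(sigma_on, sigma_off)`; the pmf has a closed form in the Kummer
  confluent hypergeometric function `1F1` with *rising*-factorial Pochhammer
  symbols, `(x)_n = x(x+1)...(x+n-1)`.  Two reparameterizations are used
  throughout: `N_sigma = sigma_on + sigma_off` (switching speed relative to
  degradation) and `f_on = sigma_on / N_sigma` (fraction of time active);
  the mean count is `rho * f_on`.
- **Negative binomial NB(r, p)**, the Gamma-Poisson mixture with mean
  `r(1-p)/p` and variance `r(1-p)/p^2`.
- **Poisson(lambda)**.

The *effective NB* is the negative binomial whose first two moments match
the telegraph model exactly:

    r_e = sigma_on (N_sigma + 1) / sigma_off,
    p_e = N(N+1) / (N(N+1) + rho sigma_off),  N = N_sigma.

It converges to the telegraph distribution at rate `O(1/N_sigma)` as
`N_sigma` grows (both laws tend to a common normal-mixed Poisson), and also
in the classical bursting limit `sigma_off -> inf` at fixed
`b = rho/sigma_off`, where the telegraph law tends to
`NB(sigma_on, 1/(1+b))`.  The first convergence is the reason NB fits can be
excellent far outside the bursting regime; the package's phase diagrams
quantify exactly where.

## Technical noise

Each true transcript is observed with a per-cell capture probability
`pcap`; observed counts are a binomial thinning of true counts.  For any of
the three models, thinning by a *fixed* `pcap` only rescales the rate
(`rho -> rho pcap`, `(1-p)/p -> pcap (1-p)/p`, `lambda -> lambda pcap`) — a
probability-generating-function substitution — so constant technical noise
never changes the model family.  Cell-to-cell *variability* in `pcap` does:
with `pcap ~ Beta(a, b)` the marginal observed pmfs are generalized
hypergeometric (`2F2` for the telegraph model, `2F1` for the NB, `1F1` for
the Poisson), and the observed Fano factor gains a term proportional to
`CV_pcap^2`, which is why capture variability pushes model selection from
Poisson toward NB.

`rho` and `pcap` enter all observed distributions only through their
product, so extrinsic noise on the transcription rate is mathematically
indistinguishable from capture variability; the package models the latter
and inherits the former automatically.

## Model selection: aeBIC

For sample-based data the package computes the ordinary BIC,
`|M| ln n_c - 2 max log-likelihood`.  To attach a *unique* best model to a
known ground-truth pmf `G` (rather than to one random sample from it), it
uses the approximate expected BIC

    aeBIC(M, n_c) = |M| ln n_c + 2 n_c eps_c(M_fit, G),

where `eps_c(M, G) = -sum_n P_G(n) ln P_M(n)` is the cross entropy and
`M_fit` minimizes it.  Since `eps_c = H(G) + KL(G||M)`, aeBIC is the
population limit of the expected BIC; it is an upper bound on `E[BIC]`
(Jensen: the expectation of a maximum dominates the maximum of the
expectation) with equality as `n_c -> inf`, and in practice agrees with a
10^3-trial Monte-Carlo `E[BIC]` to well under 1% already at `n_c = 100`
(`tests/test_acceptance.py` verifies this).  Fitting happens once per
ground truth instead of once per simulated dataset, which is what makes
20,000-point phase diagrams run in seconds.

Candidate fitting:

- Poisson — mean matching (also its population MLE up to the truncated
  support; a Brent polish is used for MLE mode).
- NB — moment matching by default (for a telegraph truth this reproduces the
  effective NB analytically); Nelder-Mead cross-entropy minimization in MLE
  mode.  The two differ by less than 1e-3 in minimized cross entropy in the
  regime where the NB is a sensible fit (`N_sigma >~ 10`); at small
  `N_sigma` the truth is bimodal and the difference is real, not numerical.
- Telegraph — always numerical cross-entropy minimization (three parameters
  are not determined by two moments), except when its family contains the
  truth exactly, in which case `eps_c = H(G)` with the truth's own
  parameters — an exact shortcut.

"Corrected" candidates integrate their pmfs over the known capture model
before fitting; "standard" candidates ignore it.  Capture parameters are
treated as known and do not count toward `|M|`.

## Burst parameters

Interpreting a fitted NB as the stationary law of the bursty birth-death
scheme gives `beta_f_hat = r_e` and `beta_s_hat = 1/p_e - 1`, while the
telegraph truth has burst frequency `sigma_on` and size `rho/sigma_off`.
The relative errors depend only on `(f_on, N_sigma)`:

    RE(beta_s) = 1 - (1-f_on)^2 N/(1+N) < 1,
    RE(beta_f) = (1 + f_on N)/((1-f_on) N),

both increasing in `f_on` and vanishing only in the bursting corner.  The
ranking protocol samples gene pairs uniformly from the corrected-NB-optimal
region, forms true and estimated burst-parameter ratios (smaller true value
in the numerator, pair order preserved), and classifies each pair as
flipped / over-estimated / under-estimated.  Ideal-condition inference is
exactly capture-independent: moment-matching the Beta-corrected NB to the
Beta-corrected telegraph truth returns `(r_e, p_e)` for every `(a, b)`.

The realistic workflow drops the assumption that the capture distribution
is known: per-cell normalization factors `beta_i = V_i / mean(V)` (total
counts `V_i`) proxy the relative capture probability, their density is
estimated by Gaussian KDE (Silverman bandwidth, clipped to the sample
range), and each gene is fitted by minimizing the negative log-likelihood
marginalized over that density with Gauss-Legendre quadrature (64 nodes by
default).  Without a known mean capture probability the absolute scales of
`rho`, `b` and `lambda` are unidentifiable — estimates are effectively
multiplied by the unknown `<pcap>`; supplying `mean_pcap` (e.g. from
spike-ins) restores absolute scale.  Burst-parameter *ratios* are unaffected
either way.

## Numerical choices

- **Telegraph pmf.**  The Kummer transform
  `1F1(s_on + n, N + n, -rho) = e^-rho 1F1(s_off, N + n, rho)` turns the
  alternating series into an all-positive one, summed in log space with an
  adaptive term count (extended until the last term is 36 nats below the
  running sum).  When the positive series itself would need more than ~700
  terms (large `sigma_off`), the pmf is instead computed by Gauss-Jacobi
  quadrature of the Beta-Poisson mixture.  The Jacobi rule is built by
  Golub-Welsch on the recurrence coefficients and normalized against the
  Beta *probability measure*, which cancels the total-mass constant and
  stays finite for arbitrarily large shape parameters (library routines
  overflow there).  Both routes agree to ~1e-12 across regimes and each
  serves as the independent oracle for the other in the tests.
- **Beta-mixed closed forms.**  The `2F2` telegraph form is evaluated with
  mpmath at elevated precision (the alternating series cancels ~0.45*rho
  digits); the NB `2F1` uses scipy with an mpmath fallback; the Poisson
  `1F1` reuses the positive-series kernel after a Kummer transform.  Scans
  use the Gauss-Jacobi mixture route (agreement ~1e-10, far faster).
- **Truncation.**  Pmfs start at `ceil(mean + 10 sd)` and are extended until
  the tail mass is below 1e-10; cross entropies are evaluated on the
  truth's support truncated at cumulative mass `1 - 1e-10`.
- **Optimizers.**  Nelder-Mead in log-parameter space; public fits use
  fatol 1e-10 / xatol 1e-6, maxiter 2000, three deterministic starts.
  Inside phase scans the telegraph MLE is warm-started from the neighbouring
  grid point with two further starts and early stop on agreement, at
  fatol 1e-9 / xatol 1e-4 — the selection threshold is `ln(n_c)/(2 n_c)`,
  orders of magnitude above that resolution.  Rates are boxed to
  `[1e-8, 1e4]` (`[1e-8, 2e3]` in the per-gene MLE): beyond
  `N_sigma ~ 1e4` the telegraph pmf equals its Poisson limit to ~1e-8, so
  the box only truncates a likelihood plateau.  Gene-level NM uses a
  function tolerance of 1e-10; tolerances below double precision cannot
  trigger and are not used.
- **Scan shortcut.**  Cross entropy is a lower bound for any fitted
  candidate (`eps_c >= H(G)`).  When the sample sizes of interest are known
  (`nc_hints`), grid points where even a perfect telegraph fit loses to
  NB/Poisson at every hinted `n_c` skip the telegraph MLE; the winner map at
  those sample sizes is provably unchanged, and hinted scans refuse to be
  evaluated at other sample sizes.
- **Ties** in model selection go to the candidate with fewer parameters.
- **Degenerate data.**  All-zero genes: Poisson/NB return boundary
  estimates, the telegraph model is flagged unidentifiable.  Under-dispersed
  truths have no NB moment match and the NB candidate is excluded at that
  point.

## Phase-diagram grids

The published area fractions come from an unspecified ~2.06e4-point grid, so
fractions are grid-dependent at the percent level.  The default grid is 206
log-spaced `N_sigma` in [0.1, 1000] x 100 linear `f_on` in [0.005, 0.995].
`scripts/acceptance.py` uses the full grid for the clean and fixed-capture
scans, 103 x 50 for the Beta-capture scan with standard candidates (the only
scan needing a numeric telegraph MLE at every point) and 72 x 36 for the
three corrected-candidate masks feeding the ranking protocol; NB fractions
move by well under one percentage point on doubling the resolution
(tested).

## What the synthetic genome does and does not emulate

`simulate_genome` reproduces the generative structure the inference assumes:
i.i.d. steady-state telegraph counts per gene (constant rates across cells),
one shared Beta- or point-distributed capture probability per cell, binomial
thinning, independence across genes.  Real data violate several of these —
cell-cycle and age structure (counts are not at a single steady state),
extrinsic variability in switching rates, gene-gene correlation, ambient
RNA and doublets, UMI collisions.  Passing tests therefore demonstrate
correctness of the method under its own model class and the identifiability
limits *within* that class; they do not certify accuracy on data where those
assumptions fail.  The defaults (1000 cells; `f_on` in {0.1..0.7} with 400
genes each; `N_sigma = 10`; `rho = 15`; Beta(15,35) capture, mean 0.3,
CV 0.21 — typical of droplet protocols) describe a realistic mid-size
experiment and are the conditions under which all reported numbers are
computed.

## Known limitations

- Absolute burst parameters in NB-optimal regions carry large errors by
  construction; only rankings (especially by burst frequency) are reliable.
- The per-gene marginalized telegraph MLE has a flat ridge toward its NB
  limit wherever the NB fits well; the reported telegraph parameters there
  are one point on that ridge, not a unique optimum (BIC selection is
  unaffected, since only the likelihood value matters).
- Bayesian credible-interval reliability filtering of `f_on` is out of
  scope; the deterministic MLE + BIC path is what is implemented.
- Multi-state (>=2-state) promoters, time-dependent solutions and protein
  distributions are out of scope.
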