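# Methods

## Model and procedure

A zero-mean multi-sinusoid signal sampled at rate `fs`,
`x[n] = Σ_k A_k cos(2π f_k n / fs + φ_k)`, satisfies an exact AR(2K)
recurrence `x_t = Σ_j a_j x_{t−j}` whose characteristic polynomial has the
roots `exp(±i 2π f_k / fs)`. The package fits the recurrence by stacking it
over a record of length `L` into an `(L−p)×p` system and taking the
least-squares solution — the pseudo-inverse solution for a full-column-rank
design, computed via LAPACK's orthogonal-factorisation least squares rather
than the normal equations (identical answer, much better conditioning).
The intercept term is excluded by default, matching the zero-mean setting;
an opt-in flag appends a ones column for processes with a non-zero mean.

Extrapolation applies the recurrence with the stochastic term set to zero,
implemented as an all-pole `scipy.signal.lfilter` driven by the constant
intercept with its state initialised from the last `p` samples. The
prediction therefore depends only on the model and those `p` samples. The
extended record's FFT has resolution `fs / (ηL)` for extension factor `η`,
which is what separates tones closer than the raw `fs / L`.

Assumptions: uniform sampling; tone frequencies strictly inside
`(0, fs/2)`; the recurrence order is at least twice the number of tones.
With measurement noise the recurrence is no longer exact, the fitted roots
move off the unit circle, and extrapolation quality degrades with horizon —
the method is exact only in the noiseless limit it was designed around.

## Design system convention

Two equivalent lag orderings exist for the stacked system (a column
reversal maps one to the other and leaves the least-squares problem and all
predictions unchanged). This package fixes one convention everywhere:
coefficient `a_j` multiplies lag `j`, so design row `r` is
`[x[p+r−1], …, x[r]]` with target `x[p+r]`.

Rank-deficient designs (all-zero or otherwise degenerate records) are
rejected with an error rather than answered with a minimum-norm solution,
since the pseudo-inverse derivation assumes full column rank and a silent
fallback would mask a degenerate input.

## Gradient-descent (ADALINE) training

`fit_ar_bp` trains the same linear neuron by deterministic full-batch
gradient descent on the mean squared error,
`w ← w + lr·(2/m)·Aᵀ(b − A w)`. Defaults `lr = 0.01`, `epochs = 200`,
zeros initialisation: the learning rate keeps the update spectral radius
well below 1 for unit-amplitude tone fixtures, and the budget is deliberately
finite — the point of the comparison is that a near-converged iterative fit
still extrapolates far worse than the closed form, because coefficient
error compounds through the recursion. A guard aborts training when the
loss exceeds 10⁶ × its initial value. Full-batch (no shuffling) keeps the
comparison reproducible; randomness enters only through the optional random
initialisation seed.

## Spectrum, peaks, and leakage correction

Spectra are unnormalised DFTs; one-sided amplitudes are `2|X_k|/N` (with
`1/N` at DC and Nyquist). Peak detection considers bins `1 … ⌊N/2⌋−1`,
takes strict local maxima above a relative floor (default 5% of the band
maximum), and enforces a minimum peak separation greedily by descending
magnitude (default 1 bin). DC and Nyquist are never reported as peaks.

Leakage correction is defined for the rectangular window only, where the
single-tone leakage follows the Dirichlet kernel. The adjacent-bin ratio
`β = |X_{k±1}|/|X_k|` gives the initial fractional offset `δ = ±β/(1+β)`,
signed toward the larger neighbour; an exact half-bin tie resolves toward
the higher bin for determinism. The offset is then polished by minimising
the residual of a two-parameter cos/sin least-squares fit over one bin
width around `k` (variable projection; `scipy.optimize.minimize_scalar`
bounded, `xatol = 1e−11` bin). The polish is what makes the noiseless
single-tone estimate exact to solver tolerance: the ratio estimate alone
carries a bias of order `δ/(2k)` from the negative-frequency image, which
is negligible for frequency readout but, multiplied by `π` through the
record, too large for high-precision phase. A final comparison against the
exact bin centre snaps full-period tones to `δ = 0`. Amplitude and phase
come from the same least-squares fit at the final frequency, with the
cosine convention `A cos(2πfn/fs + φ)` and `φ ∈ (−π, π]`.

Other windows (hann, hamming, peak-normalised) are available for spectrum
computation only.

## Pipeline and interference removal

`resolve_msw` chains fit → extrapolate → spectra → peak detection →
correction, reporting both peak lists, both resolutions and the realised
extension factor (so `extended_resolution = raw_resolution / factor` holds
by construction). Divergence warnings (any root modulus above `1 + 1e−6`)
are attached to the report; extrapolation still proceeds, since growing
transients can be a legitimate model.

`remove_interference` keeps extended-spectrum peaks whose corrected
frequency lies in a closed band, synthesises their sum over the *original*
`L` samples, and subtracts it. Post-extension estimates are used because
they are strictly sharper on noiseless fixtures; the compensation targets
the measurement, not the extrapolation. All in-band peaks are removed
jointly (mains pickup may carry sidebands). A band with no detected peak
returns the input unchanged.

Default extension factor: 10 — high enough to split sub-resolution pairs by
several extended bins, low enough that accumulated prediction error in
noisy data stays moderate. User-configurable everywhere.

## Synthetic data

The generators produce exactly what the analysis assumes: sums of cosines
with optional i.i.d. Gaussian noise (the stochastic term's distribution is
this package's choice; nothing downstream depends on it), plus an ECG-like
host built from per-beat Gaussian bumps, exactly periodic by circular
distance within the beat. Default test fixtures use `fs = 1000` Hz and
`L = 1000` samples (1 s records); the interference fixtures use a 60 bpm
template with 0.02–0.03 s bump widths, whose spectral content at 50 Hz is
~e^−20 of its low-frequency lines, so the 50 Hz estimate is uncontaminated.
What the template does **not** emulate: RR-interval variability, baseline
wander, broadband muscle noise, or amplitude modulation of the mains tone —
passing tests show correctness of the harmonic machinery, not robustness to
every artefact of clinical recordings.

## Numerical choices

- Order selection: no universal rule exists; the working default is twice
  the expected tone count, and `select_order` sweeps to the smallest order
  whose training RSS falls below `1e−10 × Σx²`.
- Rank test: `numpy.linalg.matrix_rank` at its default tolerance.
- Root-modulus warning threshold `1 + 1e−6`; root computation via the
  companion matrix (`numpy.roots`).
- CSV numerics are written with 17 significant digits and parsed through
  `astype(float)` (C `strtod`), making write→read round-trips bit-exact;
  pandas' faster CSV float path is avoided because it is not round-trip
  safe.
- Time columns must be uniform to 1e−9 relative; an explicit `--fs` must
  agree with an inferred rate to 1e−6 relative.
- The resolution bookkeeping identity `Δf_ext × N_ext = fs` is exact in
  floating point when `N_ext / fs` divides without rounding (e.g.
  power-of-two extension factors on `fs = 1000`, `L = 1000`); otherwise it
  holds to one ulp.

## Known limitations

- No regularised or Yule–Walker/Burg estimators: noisy records make the
  exact-recurrence fit a biased frequency estimator, and long
  extrapolations amplify that bias.
- Peak correction assumes a rectangular window and one dominant tone per
  bin neighbourhood; two tones inside the same extended bin remain
  unresolved, and the least-squares polish can be biased by a strong
  neighbour within a few bins (observed as ~2×10⁻³ Hz bias on the
  0.5 Hz-spaced pair — far below the tolerance it is used at).
- Streaming operation, clinical file formats (EDF/WFDB) and notch-filter
  baselines are out of scope; signals enter as plain CSV.
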