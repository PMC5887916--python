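# Methods

`scriptaniso` measures orientation anisotropy in the letters of writing
systems and asks how cultural evolution relates to it. This note records the
models implemented, the parameter choices and their rationale, the numerical
decisions, and the known limitations — in particular what the synthetic
corpus generator does and does not emulate.

## The three measures

All three measures operate on per-letter codings: counts of horizontal,
vertical and oblique straight lines plus a mirror-symmetry class. Codings
can be supplied directly (hand coding) or derived from segment geometry.

**Orientation bands.** A stroke's undirected angle is reduced modulo 180°.
It is *horizontal* if strictly less than 10° from the 0°/180° axis,
*vertical* if strictly less than 10° from 90°, *oblique* otherwise. Angles
exactly 10° from a cardinal axis are oblique (strict inequality). The four
bands cover 80/360 ≈ 22.2% of the compass: that is the chance level for
cardinality under isotropic stroke orientation. The half-width is a
parameter (`half_width`, degrees, default 10).

**Cardinality.** Per letter: the proportion of its straight lines that are
cardinal, undefined for curve-only letters. Per script: by default the
unweighted mean over letters with at least one straight line
(`letter_mean`); a `pooled` mode (total cardinal lines / total lines) is
exposed because "averaging over letters" is ambiguous when letters have
different stroke counts. The two modes differ whenever stroke counts and
cardinality are correlated across letters.

**Separation index.** A letter is *pure* when its straight lines are all
cardinal or all oblique. Under independent allocation of cardinal identity
(probability c) to each of a letter's n lines, the chance of purity is

    q(c, n) = c^n + (1 − c)^n.

The separation index is mean(observed purity) − mean(q(c, nᵢ)) over letters
with n ≥ 1, with c the script's own cardinality. It is undefined for scripts
in which no letter has more than one straight line (every letter is then
trivially pure and the index carries no information). Letters with n = 1
contribute purity 1 and chance 1; they dilute the index toward 0 but cannot
bias its sign.

*Finite-alphabet bias of the plug-in index.* Because c is estimated from
the same letters whose purity is being compared to chance, the index is not
exactly mean-zero under the independence null: Jensen's inequality (q is
convex in c) plus the coupling between the purity indicators and ĉ produce
a negative O(1/L) bias for an alphabet of L letters, ≈ −0.01 at L ≈ 20–60
and ≈ −0.002 at L = 100 (measured by simulation; the package's null-
calibration test documents this). The plug-in definition is kept because it
is the field's definition of the statistic; interpreting small positive
values therefore calls for the simulation-based null, not the nominal zero.

**Vertical-symmetry dominance.** Among letters mirror-symmetric about
exactly one axis, the share symmetric about the vertical axis. Letters
symmetric about both axes are excluded by default (`include_both=False`)
because they carry no information about the vertical/horizontal contrast;
with `include_both=True` they enter as half-vertical half-horizontal. A
script gets a score only with strictly more than `min_usable` (default 3)
usable letters.

**Geometric symmetry detector.** A glyph (a set of straight segments, x
rightward, y upward) is reflected about the vertical or horizontal axis
through its bounding-box center; it is symmetric when a one-to-one matching
(Hungarian assignment) pairs every reflected segment with an original within
`tolerance` × bounding-box diagonal, segments treated as unordered endpoint
pairs. The default tolerance is 2% of the diagonal: human coders judge
symmetry visually, so exact arithmetic symmetry is the wrong target and a
small tolerance knob is unavoidable. The detector is invariant to segment
order, endpoint orientation, translation and uniform scaling. Rotational
symmetry without mirror symmetry (Z, N, S) is classed `none`.

## Inter-rater agreement

Two coders' script-level measures are compared with the two-way,
absolute-agreement, average-measures intraclass correlation, ICC(A,k) =
(MSR − MSE) / (MSR + (MSC − MSE)/n) from the two-way ANOVA mean squares
(rows = scripts, columns = raters). Absolute agreement — not consistency —
is the right form here because a systematic offset between coders is a real
disagreement about a script's legibility. Rows with missing cells are
dropped listwise and counted.

## Mixed models and degrees of freedom

Cultural selection is tested with random-intercept linear mixed models:
y_s = μ + b_family(s) + (β · live_s) + ε_s, with b ~ N(0, τ²) and
ε ~ N(0, σ²). Script families are the grouping variable to keep shared
descent (Galton's problem) from masquerading as independent evidence.
Estimation is REML for reported estimates and CIs, ML when a null and a
status model are compared by AIC (REML likelihoods of models with different
fixed effects are not comparable; `compare_aic` enforces ML). Fits are by
`statsmodels` MixedLM behind the module's interface, with a derivative-free
fallback optimizer for boundary cases (τ̂² = 0), which are flagged, not
failed: with seven small families boundary fits are expected.

Fixed-effect t statistics, p values and 95% CIs use the grouped-data df
convention **df = N − q − (k − 1)** (q groups, k fixed-effect parameters) —
the convention of the classic nested-regression software for these models,
so an intercept-only fit over 116 scripts in 7 families prints df = 109.
This convention is knowingly anticonservative for *between-family*
quantities such as the grand intercept when there are only 7 clusters: its
CIs cover at roughly 90–92% rather than 95% (a Satterthwaite-type df would
be ≈ q − 1 = 6). It is kept for comparability; the package's own
coverage test quantifies the shortfall.

## Bayes factor

The one-sample JZS Bayes factor compares the point null δ = 0 against a
Cauchy(0, r) prior on the standardized effect (default r = √2/2). Using the
inverse-gamma(1/2, 1/2) mixture representation of the Cauchy, BF₁₀ is a
one-dimensional integral over the mixing parameter g, evaluated by adaptive
quadrature after the substitution g = z/(1 − z) maps (0, ∞) to (0, 1). The
quadrature agrees with a 10⁶-node midpoint rule to better than 0.1% and
with an independent reference implementation (pingouin) to ~1e−10 relative.
BF₀₁ > 1 favors the null; it is reported because the transformation
analyses are mostly null results. All-zero differentials are reported as
BF₀₁ = ∞ (the null is supported exactly) rather than an error.

## Lineage analyses

For each documented branching-out event, the differential is descendant
minus ancestor on a measure; events with an undefined endpoint are excluded
pairwise per measure and logged (this is why different measures have
different usable-pair counts). Differentials are grouped by ancestor script
— scripts sharing an ancestor nest together — and fed to a random-intercept
model whose fixed intercept is the directional trend, plus the JZS Bayes
factor on the raw differentials. Heritability is the ancestor-descendant
correlation (Spearman by default; Pearson available). A descendant listing
several ancestors contributes one event per ancestor, each nested in that
ancestor's group. Direction-of-reading inheritance is the share of events
in which the descendant keeps the ancestor's direction, with a per-direction
breakdown.

## The synthetic corpus generator

The generator produces corpora with the statistical structure the pipeline
expects, so the whole package is exercisable and testable without any
external download. Defaults are the scale of the cross-cultural study the
pipeline is designed for:

| parameter | default | meaning |
|---|---|---|
| `n_families` / `scripts_per_family` | 7 / (17,17,17,17,16,16,16) | 116 scripts in 7 families |
| `letters_per_script` | uniform 20–60 | alphabets/abjads/abugidas mix |
| `strokes_per_letter` | uniform 1–4 | straight lines per letter |
| `target_c` | 0.61 | grand-mean script cardinality |
| `family_sd`, `script_sd` | 0.10, 0.15 | latent cardinality spread |
| `purity_boost` | 0.16 | P(letter forced pure); drives separation ≈ +0.08 |
| `p_symmetric`, `target_vsym` | 0.35, 0.706 | symmetric letters; share vertical |
| `extinction_beta` | 2.8 | log-odds of survival per unit cardinality |
| `n_branch_events`, `lineage_depth` | 93, 4 | lineage structure |
| `transformation_sd` | 0.15 | per-branch latent drift s.d. |
| `direction_fidelity` | 0.96 | P(descendant keeps direction) |

Choices made where no value was dictated: `purity_boost = 0.16` comes from
solving sep ≈ π·(1 − q̄) with q̄ ≈ 0.49 at c = 0.61 and n uniform on 1–4,
so the default corpus sits near a separation index of +0.08;
`extinction_beta = 2.8` comes from gap ≈ σ_c² · β with
σ_c² = 0.10² + 0.15² ≈ 0.0325, targeting the ≈ 9-point live/extinct
cardinality gap such a study reports; the 50/50 horizontal/vertical split
of cardinal strokes reflects both cardinal orientations being
overrepresented without a documented imbalance.

**Mean-stationary drift.** Descendant latent features copy the ancestor
plus Normal(0, `transformation_sd`) noise. A plain clip to the feature's
bounds would make chains drift toward the interior (biasing the corpus
grand mean below `target_c`); the noise is instead drawn from a Normal
truncated to the largest window *symmetric about the current value* inside
the bounds, which preserves the conditional mean exactly. The same device
bounds the initial script-level draws.

One seeded `numpy.random.Generator` is threaded through every draw; a
config plus seed determines the corpus byte-for-byte.

**What the generator does not emulate.** (i) Heritability: with a pure
random walk on a bounded latent, parent-offspring correlations come out
high (≈ 0.8) unless the drift s.d. is implausibly large; real script
lineages show near-zero heritability, suggesting regeneration rather than
drift. Tests of heritability machinery therefore use the generator's
extremes (copying vs. independent regeneration), not its defaults.
(ii) Letter-inventory realism: stroke counts are iid per letter, with no
within-script stylistic correlation. (iii) Symmetry availability: with
`p_symmetric = 0.35` and 20–60 letters essentially every generated script
passes the >3-usable-letters cut-off, whereas real corpora lose a
substantial minority of scripts there. Passing tests on generated corpora
show the pipeline's statistical machinery is calibrated; they do not show
that real scripts satisfy the generator's independence assumptions.

## Problem sizes used in the test suite

Simulation-based tests use: 1,000 scripts for the separation null
calibration; 500 replicate corpora at the 116-script scale for CI coverage;
100–200 replicates for sign-recovery, null-covariate coverage and Bayes
factor behavior; 10⁴ letters for letter-level frequency checks; 150
replicates of 200-script corpora for mean-recovery of cardinality. These
sizes put Monte-Carlo error well below the tolerances asserted.

## Known limitations

- The plug-in separation index has the O(1/L) negative null bias described
  above; the strict "mean equals zero within Monte-Carlo error" check fails
  by design at realistic alphabet sizes and is retained as documentation.
- CI coverage under the printed-df convention is ≈ 91% rather than 95% for
  between-family intercepts with seven families (see above).
- The symmetry detector compares segment multisets; it will miss symmetries
  that hold for the drawn ink but not for the segment decomposition (e.g. a
  long stroke mirrored onto two collinear half-strokes).
- Glyph geometry carries straight segments only; curve strokes are outside
  the model (curve-only letters are valid but contribute no orientation
  counts).
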