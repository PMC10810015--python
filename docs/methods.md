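# Methods

## Scope and overall approach

`nanodamage` is a desk-scale, semi-empirical surrogate for event-by-event
track-structure simulation of DNA damage. Instead of transporting
particles and diffusing radiolysis species, it represents each stage by a
small parametric model calibrated on published numbers: per-traversal
ionization counts, low-energy electron (LEE) counts and spectra,
water-radiolysis G-values at a fixed 100 ns snapshot, per-voxel lesion
tallies, and nucleus-scale damage-site/cluster-size scoring. Everything is
driven by a single physical covariate, the track-averaged LET of the
incident particle (keV/μm), taken from a 10-row energy↔LET registry per
particle (electron energies tabulated in keV, proton/alpha in MeV;
interpolation between rows is log-log linear, a convenience — the
published conditions only use the tabulated energies).

Every constant carries a provenance tag (`paper_printed`,
`paper_anchored_fit`, `derived`, `assumption`) in the calibration registry
(`nanodamage.config`). Derived constants are recomputed from their inputs
on every build, so a config override propagates consistently.

## Voxel and energy bookkeeping

The scoring volume is a 36.0 nm³ cube (ℓ = 36^⅓ = 3.3019 nm) containing
15 bp of DNA (30 THF + 30 TMP + 15 PU + 15 PY) and 600 waters, DNA density
1.4 g/cm³. A traversal deposits `L·ℓ` eV (1 keV/μm ≡ 1 eV/nm), using the
full cube side as the chord: the irradiation geometry is a parallel,
face-normal field, and a deterministic chord keeps the surrogate exactly
calibratable. The narrow beam width (one third of the voxel side) is not
modeled geometrically; its effect is absorbed into the per-track
candidate-voxel count at nucleus scale. The deposit splits
50:50 between DNA (direct action) and water (indirect action), the ratio
implied by the hydrated/non-hydrated volume budget (600 × 0.0299 nm³ ≈
17.94 nm³ of water in 36 nm³).

## Ionizations

Mean ionizations per traversal are linear in LET, `a_p + b_p L`, with the
published slopes (α 0.10, p 0.11, e 0.14 per keV/μm). The published slopes
and the published maximum-LET point values (17.0 at 162.4; 9.4 at 81.5;
4.4 at 28.7) are inconsistent through the origin, so each line carries an
intercept fixed by the point anchor (α 0.760, p 0.435, e 0.382) — a
calibration artifact, not a physics claim. Counts are Poisson about the
mean, the standard model for independent ionization events at fixed mean.
A consequence of the intercepts: the electron line overtakes the alpha
line at 9.45 keV/μm and the proton line at 32.5 keV/μm (the data these
lines summarize show the crossovers near 8.5 and 27).

## Low-energy electrons

LEE counts are not fitted independently (absolute counts are only
available as figures); they are derived from the lesion calibration:
`N_LEE(L) = max(0, λ_p(L) − c_lin·L) / p_LEE`, where `c_lin` is the linear
(non-LEE) lesion rate and `p_LEE = (σ_SB+σ_base)·n_A ≈ 0.473` is the
per-LEE lesion probability with `n_A = 60/ℓ²` nucleotide targets per nm²
of voxel face. This guarantees LEE counts and lesion tallies are
internally consistent, and inherits the quadratic LET dependence from λ.
For electrons below ~1 keV/μm the clamp makes the count dip to zero — a
limitation of the derived route, irrelevant at the LETs where LEEs matter.

The LEE energy spectrum is a fixed mixture on [1, 25] eV — truncated
normal bump at 4 ± 1.5 eV (weight 0.25), truncated normal peak at
9.5 ± 1.2 eV (weight 0.60), shifted exponential tail from 15 eV with
2.5 eV scale (weight 0.15) — identical for all particles and LETs. The
six shape parameters are assumption-tagged: they encode the three
qualitative spectral features (broad 2–6 eV bump, dominant 8–11 eV peak,
rapid decay past 15 eV), not digitized data.

## Radiolysis G-values

G-curves (species per 100 eV at 100 ns; yields are effectively constant
after ~10 ns, so only this snapshot is exposed) are piecewise linear in
LET on [0, 300] keV/μm. Radicals (°OH, eaq⁻, H°) rise from a baseline
G₀ = 0.5 (assumption) at the published rates where printed (°OH: 0.047
proton, 0.054 alpha per keV/μm) to species peaks at 66/30/100 keV/μm,
then decline slowly (decline slopes are assumptions). H₂O₂ is zero below
the 5 keV/μm onset, rises linearly — for alphas to an assumed 1.0 at the
100 keV/μm breakpoint, then at a shallower rate — and passes exactly
through the published maxima (1.15 at 81.5 for protons, 1.44 at 262.2 for
alphas). Beyond each particle's maximum tabulated LET the curve is held
flat at its maximum: curves are extrapolations there anyway, and the clamp
keeps the electron H₂O₂ curve under its 0.3 ceiling on the whole domain.
G-values do not feed the lesion model: indirect lesion yields are fixed
measured constants, and coupling them to the G-curves would break the
lesion anchors.

## Lesion model

The per-traversal total-lesion mean λ_p(L) is a quadratic clamped at
zero, solved exactly (3×3 Vandermonde) through three anchors per
particle:

* alpha — (162.4, 39.8), (103.4, 23.1) from the nucleus table, plus the
  clustered threshold (11.5, 2.0);
* proton — (41.3, 10.8), (26.1, 6.3), (9.4, 2.0) likewise;
* electron — the threshold (7.1, 2.0) plus two low-LET anchors obtained by
  inverting the nucleus site formula against the published electron site
  counts (86.7 at LET 0.2 → λ = 0.01726; 67.9 at 0.4 → λ = 0.02758).

Exact anchoring (rather than least squares) makes the published cluster
sizes and threshold LETs reproduce identically; the remaining published
cells become genuine out-of-sample checks and agree within 2.5%. The
negative low-LET tail of the ion quadratics is clamped to zero (the alpha
quadratic is positive only above 1.16 keV/μm).

The decomposition at LET L: direct-linear `ℓL·f_dir·Y_SSB,dir`,
indirect-linear `ℓL·(1−f_dir)(Y_SSB,ind+Y_base,ind)`, and the LEE residual
`λ − (those)` clamped at zero. SSB mean `s` collects the direct+indirect
SSB terms plus the strand-break share σ_SB/(σ_SB+σ_base) = 0.4419 of the
LEE residual; base mean is λ − s.

DSBs: `min(k_D s²/4, λ/2)`. The quadratic-in-SSB form mirrors
opposite-strand pairing of independent SSBs; the publication states the
quadratic LET behavior and the thresholds but not the pairing rule, so
this form is a reconstruction. k_D is set per particle so the expected
DSB count is exactly 1.0 at the published minimum LETs (9.0/11.8/15.2);
the λ/2 cap (a DSB consumes two lesions) binds at high LET — e.g. 19.9
DSBs for alphas at 162.4 keV/μm.

Threshold solving uses plain bisection on the fixed bracket
[0.1, 300] keV/μm to 10⁻³ keV/μm, after asserting monotonicity of the
target quantity on the bracket.

Stochastic voxel realizations: total ~ Poisson(λ); each lesion is an SSB
with probability s/λ else a base lesion; SSBs fall on either strand with
probability ½; the sampled DSB count is min(strand-1 SSBs, strand-2 SSBs),
which respects DSB ≤ ⌊SSB/2⌋ draw by draw.

## Nucleus scale

A 4.0 μm nucleus receives a fixed 260 keV (nominally 2.0 Gy; the pair is
taken as printed configuration, not recomputed from sphere mass — a
unit-density 4 μm sphere would imply a different equivalence). Tracks
cross the full diameter, `n_tracks = 260/(4L)` — 325 tracks at the
0.2 keV/μm electron minimum, matching the published "about 320"; a
mean-chord (⅔d) convention would not. Each track exposes N_v = 4
candidate voxels, a value derived from the published table's
self-consistency (printed sites equal 4·n_tracks within ~1% for every
medium/high-LET row), not printed directly.

Two site-counting modes exist because no single formula reproduces both
the ion rows (sites ≈ 4·n_tracks even at λ ≈ 1.4) and the electron rows
(sites ≪ 4·n_tracks): `table2_compat` (default) counts all four candidate
voxels of any track that produced a lesion, sites = n_tracks·4·(1−e^(−4λ)),
cluster size = λ per candidate voxel; `principled` counts individually
damaged voxels, sites = n_tracks·4·(1−e^(−λ)), cluster size =
λ/(1−e^(−λ)) per damaged voxel (→ 1 as λ → 0). Compat sites always
dominate principled sites.

The stochastic nucleus simulator draws ⌈n_tracks⌉ tracks of Poisson voxel
counts and scores the final track with the fractional weight
n_tracks − ⌊n_tracks⌋, so per-repetition deposited energy is exact and
repetition means converge to the closed forms without bias.

## What the stochastic generator does and does not emulate

The Poisson/binomial machinery reproduces counting statistics at the
calibrated means — enough to validate estimator convergence, seed
determinism and the scoring conventions. It does not emulate spatial
correlation along a track, LET straggling, chemistry time dependence, or
inter-track effects (negligible at these fluences: nominal inter-track
distances are ~0.1 μm at the lowest LET). Passing tests therefore show
internal consistency with the published summary numbers, not agreement
with microscopic track-structure data.

## Known limitations

* The compat site formula with the anchored proton quadratic over-predicts
  damage sites for protons below ~2 keV/μm (LET 1.2: 90.6 vs the published
  47.4; LET 0.7: 38.1 vs 47.1). The quadratic is anchored at
  9.4–41.3 keV/μm and extrapolates poorly downward; the published pair is
  nearly flat in LET, which no monotone λ(L) of this family can produce.
  All other published nucleus-table cells reproduce within 2.5%.
* Figure-only quantities (absolute radical amplitudes, post-peak slopes,
  absolute LEE counts, spectrum shape parameters) are assumptions; only
  their qualitative features are constrained.
* The electron lesion quadratic has a small positive intercept
  (λ(0) ≈ 0.0097) forced by its site-inversion anchors, so electron DSB
  and lesion means at LET → 0 are ~10⁻⁵–10⁻², not exactly zero.

## Problem sizes and randomness

Default statistical checks use 10⁵ Poisson draws per LET for
slope-recovery regressions, 2×10⁴ draws per configuration for voxel-damage
means, and 600–1000 repetitions for nucleus simulations — sizes at which
Monte-Carlo standard errors are a few per mil of the calibrated means.
All randomness descends from one root seed through named substreams
(`numpy.random.SeedSequence` with a per-module spawn key), so adding draws
in one module never perturbs another and identical seed + config gives
byte-identical outputs.
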