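# Methods

`inkdose` estimates how intradermal tattoo pigments perturb skin dose
under megavoltage external-beam radiotherapy. It chains five stages: ink
chemistry → mixture materials → a layered voxel skin phantom → simplified
Monte Carlo transport → depth-dose / DEF analysis. This note records the
models, the defaults and why, the numerical choices, and the limits of
what the simplified engine can show.

## Ink chemistry

Commercial ink assays report elemental content in ppm of *wet* ink.
Because only the solid pigment is retained in the dermis, wet
concentrations are converted to a dry basis by dividing by the
dry-matter fraction `f_dry` (default 0.47; surveys report 0.31–0.62, and
the random-ink generator draws uniformly from that range).

The assay fixes the metal content but not the compound amount, so the
closure of the dry pigment to unit mass is a genuine modeling choice.
Two closures are implemented:

* **compound** (default): trace metals stay elemental at their
  dry-basis concentration and the remaining mass *is* the dominant
  compound, split stoichiometrically — brown becomes essentially Fe₂O₃
  plus traces, orange Al(OH)₃, black carbon. This is the reading under
  which the brown pigment really is "Fe₂O₃-dominant", the compound
  bulk-density assignment (5.3 / 2.4 / 1.8 g/cm³) is self-consistent,
  and the strong 18 MV pair-production response of the brown layer is
  possible at all.
* **binder**: the compound amount is derived from its metal's dry-basis
  assay via stoichiometry (Fe₂O₃ = Fe × 159.69/111.69, Al(OH)₃ =
  Al × 78.00/26.98) and the residual mass is a generic organic binder
  modeled as carbon. This is the stricter arithmetic reading of the
  assay, but it leaves the "brown" pigment 73% carbon — a low-Z
  material that cannot produce the high-Z interaction signature the
  study design targets.

The active closure is flagged in run provenance.

REACH compliance verdicts compare **wet-basis** ppm against the limits
(the basis the published comparison uses); a dry-basis comparison would
be stricter by 1/`f_dry`. Entries below the limit of quantification are
stored as 0 ppm with an explicit below-LoQ flag.

## Mixture materials

Two rules generate every material: volume-fraction density mixing,
ρ_mix = v·ρ_ink + (1−v)·ρ_dermis, and mass-fraction weighting,
w_i = v_i ρ_i / Σ_j v_j ρ_j. The dermis partner is always the reticular
dermis at 1.1 g/cm³. Internal values keep full precision; comparison
with the printed mixture-density table applies Python's builtin
`round(x, 1)` — correct round-half-even on the computed double — which
reproduces all 21 printed cells (decimal half-up does not: the exact
midpoints 2.15 and 4.25 print as 2.1 and 4.2).

Skin layers share one elemental composition (O 62, C 20, H 10, N 3 wt%
plus ~5% trace elements including Ca, Zn and Fe, normalized from a
printed sum of 0.999) and differ only in density.

## Phantom

Depth z runs downward from the surface in mm. Six epidermal sublayers
(100.1 µm), a 0.4 mm papillary dermis and a 1.9 mm reticular dermis tile
[0, 2.4001] mm; a 0.3 mm tattoo sublayer sits at 1.25–1.55 mm. Voxel
intervals are half-open [top, bottom): a boundary point belongs to the
deeper layer. Choices where the source material is silent:

* water backing 10 cm (saturates backscatter at these energies);
* lateral extent 3×3 cm, wider than the 1×1 cm field, to keep lateral
  scatter inside the geometry;
* scoring mesh 0.1 mm in depth (24 bins over 0–2.4 mm) and 2 mm
  laterally; quadrant runs score on 2.5 mm bins so every lateral bin
  nests inside a single 0.5×0.5 cm quadrant.

## Transport engine

A deliberately small surrogate for a general-purpose MC code, keeping
only the interaction physics the dose-enhancement findings rest on.

**Photons** (Woodcock/delta tracking through the layered geometry):

* Compton scattering: exact Klein–Nishina total cross section per
  electron times electron density; composition-rejection sampling of the
  scattered fraction; electron direction from momentum conservation.
* Photoelectric: fitted Z^4.5/E³ power law anchored to the packaged
  water reference at 0.1 MeV; negligible above ~1 MeV but retained for
  scattered photons.
* Pair production: zero below 1.022 MeV; above threshold a
  Bethe–Heitler-style Z(Z+1)/A scaling whose energy shape is anchored to
  the packaged water attenuation reference. The available energy is
  split uniformly between e⁻ and e⁺, emitted at the characteristic
  m_ec²/E angle; the positron annihilates at rest into two 511 keV
  photons. Coulomb/screening corrections for very high Z are not
  modeled (the packaged pigments are low/mid-Z).
* Rayleigh scattering is omitted (no energy transfer; <4% of
  attenuation at the relevant energies).

**Electrons and positrons** (class II condensed history):

* Restricted Berger–Seltzer (Møller) collision stopping power with
  Bragg-additivity mean excitation energies and an asymptotic
  density-effect correction; knock-on electrons above the regional
  threshold are produced explicitly by Møller sampling.
* Multiple scattering is split at 0.25 rad: soft collisions form a
  Highland Gaussian per step — log width correction evaluated on the
  electron's CSDA-scale path (Lynch–Dahl practice), variance scaled to
  the soft fraction of the screened-Rutherford angular variance so the
  two parts are complementary — while hard elastic events beyond the
  split angle are sampled singly from screened Rutherford with the
  Mott spin factor. The hard tail supplies genuine backscatter that a
  Gaussian cannot.
* Radiative loss is continuous and *not* rescored (bremsstrahlung
  photons overwhelmingly leave the 2.4 mm slab); reabsorption is a
  known ~1–2% fidelity limit.
* Positrons transport as electrons and annihilate at track end.

**Cutoffs and steps.** Electrons below 50 keV (10 keV inside the
1.25–1.55 mm tattoo band, emulating the finer upstream production cut)
and photons below 10 keV deposit locally. Steps are capped at
min(0.02 mm inside z<3 mm, 5% energy loss, distance to the next layer
boundary); below 3 mm the geometric cap relaxes to 0.5 mm. Electron
histories are terminated 10 mm below the surface and at the lateral
phantom edge — several backscatter depths away from the scoring slab.

**Scoring.** Dose-to-medium, plus a dose-to-water channel in which every
deposit is weighted by the water/medium unrestricted mass collision
stopping-power ratio at the depositing electron's energy (the
convention standard skin dosimetry reports; an early fixed-1 MeV-ratio
variant differed by ~2% and was replaced by the energy-dependent form).
Dose-to-water is the default `dose` array. Per-voxel uncertainty uses
the batch method with 10 batches.

**Randomness.** Counter-based: history *i* of seed *s* uses an
xorshift64* stream seeded by splitmix64(s, i), so results are
bit-reproducible and independent of execution order.

**Beams.** "6 MV"/"18 MV" photon and 6/18 MeV electron beams are
monoenergetic with a Gaussian spread of σ = 2% of nominal (the spread is
configurable; no spectrum is packaged). Default source: parallel beam
collimated to 1×1 cm² at the surface — at SSD 100 cm the divergence
across 2.4 mm is negligible — with a point-divergent mode available.

## Analysis

Depth dose D(z) is the lateral mean over the field at each depth;
integrated skin dose sums the 24 bins; DEF(z) = D_tattoo(z)/D_control(z)
with quadrature error propagation. Summary statistics: peak DEF over
0–2.4 mm, tattoo-layer mean over the bins covering 1.2–1.6 mm (the
0.1 mm mesh cannot isolate 1.25–1.55 exactly; the band is recorded in
provenance), integrated-dose ratio, and the minimum over 1.6–2.0 mm
("immediately beneath the pigment layer" — a documented convention).
Depth profiles default to the full field, matching the published
averaging; a central-region mask is available for penumbra-free curves.

## Problem sizes

Desk-scale runs use 10⁶ primaries per configuration (per-bin DEF noise
roughly 1–4% for photons, <1% for electrons), against ≥10⁷ at full
scale; the acceptance tolerances are widened accordingly. A 10⁶-history
run of any modality completes in well under 15 minutes on one CPU.

## What the tests do and do not show

The synthetic generators (random inks, toy dose grids) exercise the
algebraic contracts — normalization, mixture rules, profile/DEF
arithmetic — not the realism of any particular ink. The transport
oracles check water attenuation, Klein–Nishina sampling and CSDA ranges
against packaged compilation values; they do not certify Geant4-grade
accuracy. A simplified surrogate of this kind reproduces the
qualitative structure of the published findings — photon ≫ electron
perturbation, the brown > orange > black composition ordering, loading
monotonicity, depth confinement, the 18 MeV electron dose deficit — and
the photon peak DEF and electron-beam magnitudes to within the stated
engine tolerance. Its DEF curve is, however, broader across the pigment
layer than the published one: the tattoo-band *mean* DEF comes out
higher than the published 53%/62% figures, whose exact averaging region
is not defined upstream (the depth-summed integrated ratio, by
contrast, lands near the published 6 MV mean). The enhancement in this
engine is the areal-density buildup of secondary electrons plus
hard-elastic obliquity and backscatter; interface physics below the
0.1 mm bin scale is not resolved. Known limitations otherwise: no
Rayleigh scattering, no atomic relaxation/fluorescence, no
bremsstrahlung photon transport, no phase-space sources, no
protons/ions, no variance reduction.
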