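# Methods

This note documents the models behind `pulsefate`: what each generator
emulates, the analysis contracts, the defaults and why they were chosen,
and what passing tests do and do not establish about real microscope
data.

## Lentiviral colour-mix model

Each founder cell draws an independent Poisson number of vector
integrations per channel (default mean 1.8 for each of R, G, B); a
founder with zero integrations in all channels would be colourless and is
resampled. Every integration expresses at an independent lognormal level
(mean 1, CV 0.35), and the channel intensity is
`background + expression_scale * sum(expression_i)`, clipped to the
16-bit range. Defaults (scale 9000, background 300) spread founder
colours across the quantisation lattice.

Two constraints implement the premise that each clone carries a unique,
recognisable colour code: a founder whose quantised 512-class colour
collides with an earlier founder is resampled, and each channel must sit
at least `bin_margin` (default 800 grey levels) away from an interior
quantisation-bin edge, so moderate measurement noise cannot flip a
clone's class. With the default 64 founders and Dirichlet(60) clone
weights, every clone holds ~1.6% of a 10,000-cell population — far above
the 0.1% positivity threshold — which is what makes the untreated
control resolve into exactly 64 positive clonal colours. Rendered images
draw cells as flat discs of the founder colour over a constant background
with Gaussian camera noise; the table route carries the exact founder
colours (noise enters only through imaging).

What this does not model: spectral bleed-through between channels,
intra-clone expression drift, cell shape, or illumination gradients
beyond a smooth background. Clone-calling results on real images will
additionally depend on segmentation quality and unmixing.

## Clonal-colour analysis

The image stage mirrors the conventional workflow: per-channel
background subtraction with a rolling paraboloid (ellipsoid kernel of
width 2r and height r/2; a fast morphological-opening fallback agrees
within 5% on reference instances), disc mean filter (default radius 5),
regional-maxima cell detection on the channel sum (h-maxima transform
with a prominence tolerance; maxima closer than 5 px are merged keeping
the brighter), and disc-ROI sampling of the *raw* image (default radius
5 px, clipped at borders). Records whose R, G or B mean falls outside
per-channel quantile bands (defaults 1%/99%) are removed with a logged
reason; the exclusion rule is configurable because the original
"too high or too low" criterion is qualitative.

Quantisation uses 8 equal-width bins per channel over the fixed range
[0, 65535]; the class index is `64*bin_r + 8*bin_g + bin_b`, giving 512
classes. Fixed-range (rather than per-dataset min-max) binning keeps
class identities comparable across images and runs. The 64 most frequent
classes become reduced groups (ties broken by ascending class index);
coverage is the assigned fraction. Clone fractions are computed over all
cells including UNASSIGNED, and a clone is positive iff its fraction is
strictly greater than 0.1%. Raising the threshold can only lose clones;
raising k can only increase coverage; both monotonicities are tested.

## FUCCI trajectory generator

Tracks span 72 h at a 30 min cadence (the generator accepts other
cadences; published protocols vary between 10 and 30 min). Reporter
semantics: red high through G1; at the G1/S transition red decays while
green rises, giving a ~2 h yellow overlap window; green persists through
S/G2/M; both reset at anaphase with a one-frame colourless gap. Nuclear
area doubles across each cycle and halves at anaphase, which is what the
division proxy in the analysis layer keys on.

Cell-cycle durations default to G1 24 h, S 7 h, G2 3 h, M 1 h with a
0.15 CV per phase and a 30 min NEBD-to-anaphase mitotic length. Under
exponential growth the steady-state G1 occupancy is
`2*(1 - 2^(-G1/T))` = 0.758 with these means, inside the 70-80% G1
window observed in untreated tumours — that observation, not a measured
duration set, fixes the G1 share. Cells that keep cycling after a pulse
do so with a 1.4-fold lengthened cycle, reflecting the post-damage
delays seen in treated cultures.

Fate scripts are applied exactly from count-based allocations (no
sampling; order shuffled by seed). The four reference cohorts encode the
observed synchronise-and-pulse outcomes at n = 50: G1 exposure gives 7
single divisions and no multi-dividers, with the remainder split 40
G2-exit / 3 persistent S/G2 arrest (the split beyond "the majority
underwent G2-exit" is an assumption and is configurable); palbociclib
and thymidine G1/S exposure give 13 and 16 proliferative cells; late-S
exposure gives 4 cells completing exactly two divisions
(`prolif_divisions=2`) with nearly all others dividing once and then
arresting. Arrest-linked enlargement is exponential at 1.5-fold per
24 h, capped at 6-fold, accumulating from exposure (or from the last
division for arrest-after-mitosis fates); the 1.5 rate places 72 h
cells at ~3.4-fold, inside the reported 2-6-fold range, and the cap is
the top of that range.

## Fate classifier

Phase calling thresholds both reporters (default 0.2 against a unit
amplitude) with run-length hysteresis (runs shorter than 2 frames merge
into the preceding phase). The decision order is: death (before/after
mitosis by division count) > two or more divisions > one division >
G2-exit (a green period of at least 20 h resolved into red without
mitosis) > G1 arrest > persistent S/G2 arrest. One-division tracks that
end in a terminal G1/red arrest of at least 8 h are called G1_AAM
(arrest after mitosis) rather than SINGLE_DIV; without this distinction
the arrest-after-mitosis category could never be produced. The 20 h
G2-exit minimum is an operational choice (the qualitative description is
"prolonged S/G2 arrest"); lowering it can only add G2_EXIT calls, which
is tested as a monotonicity property. Events at exactly the 72 h horizon
count (closed interval). All-GAP tracks are flagged UNCLASSIFIABLE and
excluded from cohort fractions with a logged count.

On 500 synthetic tracks at the default trace noise (additive Gaussian,
sd 0.05) the classifier reproduces fate labels at >= 98% accuracy with
exact division counts; this certifies the classifier against the
generator's trace model, not against tracking errors, segmentation
failures or reporter silencing in real movies.

## Population simulation

Untreated growth is an age-structured branching process: each cell draws
its own phase durations, initial ages follow the exponential-growth age
distribution, and divisions spawn two daughters. The FUCCI read-out
(red/yellow/green counts, fractions summing to one) is evaluated on a
2 h grid. A pulse at t = 0 assigns each cell a fate from a
phase-at-exposure fate map whose columns are the four reference cohorts
plus a G2/M column (mostly one division then arrest). With functional
p53, S/G2-arrested cells undergo a delayed G2-exit (normal, mean 96 h,
sd 24 h), reproducing the gradual day 3-7 decline of the green
population and the >90% red state at day 7; without p53 the map shifts
arrest/exit mass towards continued division and post-mitotic death, and
S/G2-arrested cells persist. Death removes cells from the counts.
Reported nuclear areas are the arrested-cell mean (enlargement as above)
and the cycling-cell mean (area 2^(age/T) relative to a 140 um^2
baseline).

## Focus kinetics and detection

Latent per-frame counts follow phase targets with finite
appearance/resolution rates (35/h up, 4/h down): undamaged replication
targets ~12 foci (always below 20); G1-exposed cells ramp to ~100 on S
entry and resolve slowly during the ensuing arrest; early-S-exposed
cells burst to ~100 in the first S, then decline by 0.4-fold per
generation; post-mitotic G1 nuclear bodies are few and grow from ~1 um^2
in daughters towards the <= 5 um^2 control regime in grand-daughters.
Counts reset at mitosis (damage repartitions into the daughters' G1
bodies). Rendered frames place foci as flat discs (minimum ~2 px) with
blue-noise separation inside the nucleus disc; focus size and count
trade off so that dense bursts remain resolvable, matching the
inverse relation seen in the data. Detection thresholds each nucleus at
median + 3 * 1.4826 * MAD of in-mask intensity — affine-equivariant, so
counts are invariant to intensity rescaling — and keeps components of at
least 0.08 um^2 (~2 px at 0.2 um/px), excluding sub-resolution specks.
PCNA sub-staging uses focus count, mean area and the median radial
position: <5 foci = nonS, mean area >= 0.6 um^2 = late S, radial median
>= 0.62 of the nucleus radius = mid S, otherwise early S. These
thresholds are this package's operational contract, matched to the
generator's archetypal patterns; applying them to other imaging setups
requires recalibration.

## Size gating

Nuclear areas are pixel counts times the squared pixel size. The
stable/enlarged gate is the 97.5th percentile of the untreated-control
area distribution — a conventional two-parameter control gate in the
absence of instrument-specific settings — and depends on the control
only. Fold changes are ratios of means with a seeded bootstrap interval.
The flow-cytometry origin of the sorting step (FSC/SSC with doublet
exclusion) is replaced by imaged nuclear area; doublet exclusion is out
of scope.

## Problem sizes and numerical choices

Default verification sizes: 10,000 cells for clone calling, 50-track
cohorts (500 tracks for classifier certification), n0 = 2000 for
population runs of 5-7 simulated days averaged over three seeds, and
512 x 512 rendered clone images. All randomness flows from explicit
seeds through `numpy.random.Generator` (split per track/cell); identical
seeds give byte-identical outputs. Degenerate inputs are defined
behaviour: empty populations render background-only images, empty point
lists give empty tables, all-rejected filters and empty masks raise
configuration errors naming the offending parameter, and quantile ties
or rank-k ties break deterministically (ascending colour-class index).

## Known limitations

Synthetic traces omit tracking errors, lineage misassignment,
photobleaching, focus drift and reporter silencing; rendered images omit
cell shape, spectral overlap and uneven illumination. The population
model treats fates as fixed at exposure and ignores microenvironmental
feedback. Classifier and detector accuracies quoted here are therefore
upper bounds for real data, and the in vivo, sequencing-based and
flow-based read-outs of the underlying biology are outside the package's
scope.
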