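# Methods

## Model overview

`scleraxl` solves a one-dimensional multilayer reaction–diffusion system for
methylene-blue (MB) photocrosslinking of the posterior eye wall. The spatial
domain runs anterior → posterior from the retinal pigment epithelium (RPE) /
choroid interface (x = 0): choroid, sclera, Tenon's capsule, then the
retrobulbar MB injection reservoir created by a 100 µl injection. The RPE is
not part of the diffusion domain; it enters only as a static optical slab
(melanin absorption plus a reflected fraction Φ_Fundus). Each layer is tiled
by equal-thickness finite-volume nodes; species concentrations live at node
centers and all distances are reported from the RPE.

Three species presets (rat, minipig, human) carry the anatomy and
composition: layer lengths, the five scleral and choroidal amino-acid
concentrations (His, Met, Trp, Cys, Tyr), melanin in RPE/choroid/sclera,
baseline dissolved ³O₂ at 21% inspired O₂ in choroid and reservoir, tissue
densities and the peripapillary frustum volume used to convert mean
concentrations to total moles. A shared-constants preset carries the
photochemical and transport parameters (quantum yields, decadic molar
absorptivities, diffusivities, dimerization constant, rate constants
k1–k14). Both presets ship as human-readable YAML and every field can be
overridden.

## Photochemistry

All reactions are elementary mass-action terms evaluated per node over 33
chemical pools: 8 mobile (MB monomer, dimer, triplet, semi-reduced, leuco,
degraded, ³O₂, ¹O₂) and 25 immobile (per amino acid: ground, radical,
oxidized, type I crosslink, type II crosslink). Keeping the crosslink and
oxidized sinks per amino acid makes per-AA conservation

    ground + radical + oxidized + XL_I + XL_II = const (per node)

exact, which the property suite asserts to 1e-8 relative.

Excitation is first-order in ground-state monomer with rate constant

    Γ = Φ_MBT · ln(10) · ε_MBM · I / (N_A · h c / λ),

i.e. the volumetric photon-absorption rate of the monomer (decadic
absorptivity, hence the ln 10) times the triplet quantum yield;
Γ = 0.205 s⁻¹ at the baseline 424 mW cm⁻². The triplet then partitions
between solvent quenching (k3), collisional quenching by ground-state MB
(k4), radical-forming quenching by amino acids, and energy transfer to ³O₂
(k9, the type II gateway). One crosslink is scored per reacting amino-acid
event — the accounting under which "site utilization" against the total
amino-acid concentration is meaningful.

A design point that was genuinely open: the tabulated triplet-quenching
constants for Met and Cys are labelled physical (quencher-conserving), yet
the type I pathway is described as involving all five amino acids, and the
crosslink budget only closes if Met and Cys feed the radical channel. The
package therefore routes k4(Met) and k4(Cys) as chemical quenching
(³MB + AA → MB_semireduced + AA•) by default; the strictly physical reading
is available via `SharedConstants(triplet_aa_quench_chemical=False)`.
Quenching by the MB monomer itself is always physical.

MB photodegradation (¹O₂ + MB → degraded MB) exists in the network but
defaults to rate 0 — no rate constant for it is tabulated — so the degraded
pool stays empty unless `k_deg` is supplied.

## Light

Decadic Beer–Lambert attenuation with melanin (static per layer; zero in
Tenon and reservoir), MB monomer and MB dimer (dynamic) as absorbers; no
scattering, no return pass of the reflected fraction. Node intensities are
evaluated at centers by attenuating half a slab in, half out, which makes
attenuation exactly compositional across slab unions (asserted to 1e-12).
The field is recomputed at every RHS call, so MB consumption dynamically
deepens light penetration ("photobleaching-limited" propagation). Excited,
semi-reduced, leuco and degraded MB are taken as transparent at 660 nm —
only the three tabulated absorptivities participate.

## Transport

Mobile species diffuse by finite-volume Fick's law with harmonic-mean face
diffusivities: MB-family species (monomer, dimer, semi-reduced, leuco,
degraded) at D_MB (tissue and reservoir values differ), ³O₂ at D_O2
everywhere. ³MB and ¹O₂ do not diffuse: their chemical lifetimes (≤ 0.1 ms)
are orders of magnitude below the per-node diffusion time, so transport of
the excited states is negligible. Amino acids and their products are
collagen-bound and immobile.

Boundary conditions for the treatment geometry: no-flux for MB at the RPE
face (the RPE as barrier); a Robin clearance sink for all MB-family species
at the posterior face, with resistance X_Retro / D_MB,res (plus the boundary
half-node) to a zero-concentration retrobulbar bath; Dirichlet ³O₂ at both
faces — the choroidal vasculature anteriorly and retrobulbar tissue
posteriorly — at baselines scaled linearly through the origin with per cent
inspired O₂ (0% → 0 M; 21% → the measured anchors; 300% = hyperbaric pure O₂
by extrapolation). Richer piecewise-linear anchor sets can be supplied.
Initial ³O₂ interpolates linearly across sclera/Tenon between the two
anchors; injected MB starts in the reservoir at its monomer/dimer
equilibrium partition (K_D [M]² = [D], monomer-equivalents conserved).

## Numerics

Method of lines over all nodes × 33 pools (3135 unknowns at the default
12/28/7/48 mesh), integrated with SciPy's BDF and an analytic sparse
Jacobian assembled per call from three parts: dense per-node reaction
blocks, constant tridiagonal diffusion entries with their boundary
diagonals, and the nonlocal light-shading lower triangle (MB and dimer at
node j attenuate excitation at every node i ≥ j). The Jacobian is verified
against 3-point finite differences in the test suite. Defaults
rtol = 1e-7, atol = 1e-15 M (excited-state concentrations reach 1e-12 M);
at these settings a further 10× tightening moves totals by ~1e-8 relative.
Trial states are clamped to [0, 1e3 M] inside the RHS — the lower bound
guards mass-action positivity, the upper bound keeps diverged Newton trial
steps from overflowing the quadratic terms — and any clamping beyond
round-off is reported in the solver diagnostics.

Node counts: the published tissue discretization (12 choroid / 28 sclera /
7 Tenon) is kept. The reservoir count is not published; 48 nodes is the
package default because the early injection-interface flux has a √t
singularity and coarser reservoirs leave totals grid-sensitive (with 12
nodes a 3× refinement moved rat totals by 16%; with 48, by < 4% for every
species). Snapshot defaults 0, 0.5, 3, 10, 30 min; the stored time grid
adds a uniform 10 s series for kinetics curves.

The pipeline draws no random numbers; results carry a SHA-256 hash of the
resolved configuration.

## Reported metrics

Averaging domain for all tissue metrics is choroid + sclera + Tenon,
thickness-weighted; the reservoir is excluded. Total moles = mean crosslink
concentration × frustum tissue volume. Site utilization divides by the
"crosslink sites possible" concentration: the length-weighted mean of the
summed five-amino-acid concentrations, with Tenon assigned scleral
composition (its own is not characterized — the assignment that reproduces
the published site concentrations for all three species within 0.5%).
MB speciation fractions are over species concentrations with the dimer
counted once (not in monomer-equivalents); the monomer-equivalent total is
also exported for mass-balance checks. "Posterior edge of sclera" means the
posterior-most scleral node center. Peak location is the node center of the
maximum final crosslink concentration, also expressed as a fraction of
scleral depth.

## Sweeps and optimization

The sweep driver runs the Cartesian product of injected MB (mM) × fluence
(mW cm⁻²) × per cent inspired O₂ per species, recording totals,
utilization, peak depth and pathway split per cell; failed cells are
recorded without aborting. The optimum is the grid argmax of total
crosslinks, ties broken toward the mildest treatment (lower MB, then
fluence, then O₂). Default anchors are 0.3/3/30/100 mM, 10/424/1000
mW cm⁻², 21/100/300%.

## What the model does and does not capture

The simulator reproduces the study conditions as a deterministic forward
model; there is no data fitting anywhere. Qualitative behaviours emerging
from the defaults include: light entering the sclera ordered
rat > human > minipig (thin rat choroid; low-melanin human choroid;
minipig both thick and melanotic) with a shallower per-µm decay in the
low-melanin minipig sclera; the rat MB front staying more posterior than
the human front; a transient posterior ³O₂ elevation from the injected
reservoir that relaxes toward the vascular profile; type I dominance of
crosslinking; a rat-specific decline of crosslinking from 30 to 100 mM MB
(dimer shading and triplet self-quenching) while minipig and human still
gain; and near-zero crosslinking below ~0.1 mM MB.

Known limitations: the geometry is a 1D axis through the treated tissue (no
annular-beam or spherical-shell effects); no scattering, heating, pH or
ionic-strength dependence; no melanin photochemistry; no convective or
episcleral clearance; anatomical variability between individuals is not
modelled. Excitation magnitude deserves a caveat: the photon-to-triplet
conversion is computed from first principles (printed absorptivity, quantum
yield and irradiance), and with it the simulated totals in the strongly
excitation-limited minipig and human baselines sit well below the published
values with the same parameter set, while delivery-limited quantities (rat
baseline totals, utilization, sites-possible, the optimum's argmax
structure) agree. Comparisons against the published excitation-limited
numbers should bear that systematic difference in mind.
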