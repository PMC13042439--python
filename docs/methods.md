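# Methods

This note documents the models, numerical choices and known limitations of
`qmregion`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## The tight-binding engine

The electronic model is deliberately minimal: one s-like orbital per atom
in an orthogonal basis. For atoms a, b at distance r_ab,

    H_ab = β₀ exp(−κ (r_ab − r₀))        for r_ab ≤ r_hop (else 0)
    H_aa = α_a − Σ_b γ_ab q_b − Σ_m γ_am Q_m

with the Klopman–Ohno kernel γ_ab = k_e / √(r_ab² + (k_e/U_avg)²),
γ_aa = U_a, k_e = 14.399 eV·Å, and Q_m external point charges. Atomic
charges are Mulliken populations relative to the element's valence count
(q > 0 = electron-deficient; a positive external charge lowers nearby
onsite levels, so at large R every level shifts by −k_e/R). Orbitals are
filled aufbau with integer occupations (2 per orbital, one singly occupied
for odd counts; degenerate frontier levels resolved by index after the
ascending eigenvalue sort). The self-consistent-charge (SCC) loop mixes
charges linearly until max|Δq| < 10⁻⁶ e.

The total energy is the variationally consistent

    E = Tr(P·H₀) + ½ qᵀΓq + Σ_a q_a V_ext,a + E_rep + E_disp

with Born–Mayer repulsion Σ A_ab e^(−r/ρ_ab) and damped dispersion
−Σ C6_ab/(r⁶ + r_damp⁶), reported as separate components. (A formulation
that adds ½qᵀΓq to the *band eigenvalue sum* would double-count the charge
interaction, because the eigenvalues already contain the −Γq potential;
the density-matrix form above is the one whose gradient reproduces H.)

### Parameters and units

Å and eV internally; interface energies in kcal/mol via 1 eV = 23.0609
kcal/mol. The shipped table covers H, C, N, O, Si, Al, F, Cl, Br, I.
Onsite energies α track electronegativity (−6.5 eV for Al to −14.5 eV for
F); electron-rich elements contribute two valence electrons, electropositive
ones one, so mixed clusters open finite gaps and transfer charge in the
chemically expected direction.

Two deliberately "effective" choices:

- **Screened Hubbard U (2.5–4.7 eV).** With a single orbital per atom and
  integer occupations, free-atom hardness values (7–13 eV) make the charge
  response stiffer than the level spacing: the SCC map develops
  HOMO/LUMO crossings at which no integer-occupation fixed point exists,
  and the cycle oscillates regardless of mixing. The screened values keep
  the charge-transfer physics while keeping the cycle contractive.
- **Short-ranged repulsion (ρ ≈ 0.25–0.30 Å)** crossing dispersion near
  2.9 Å, so bonded distances are repulsion-balanced while van der Waals
  contacts beyond ~3 Å are net attractive — the property that makes a
  host cavity bind a neutral guest.

### SCC numerics

Linear mixing starts at 0.3 and is halved (floor 0.01) whenever the
residual fails to improve for 8 iterations — the standard cure for
over-relaxation 2-cycles; up to 500 iterations are allowed so damped runs
can still finish. Non-convergence is reported on the state
(`converged=False`), never hidden; it genuinely occurs for systems whose
self-consistent solution sits on a frontier-orbital crossing (odd-electron
assemblies, symmetric charged hosts), which integer occupations cannot
represent. All defaults are configurable on `ToyParams`.

## The FMO layer

FMO1 solves every QM fragment in the point-charge field of all other
fragments (QM: current Mulliken charges; MM: frozen charges) and sweeps in
ascending fragment id (Gauss–Seidel) with damping 0.5 until the monomer
charge vector is sweep-to-sweep stable (10⁻⁶ e). The embedding uses the
same Klopman–Ohno kernel as the intra-fragment Hamiltonian, as FMO-DFTB
does. MM fragment charges default to a prior all-QM run of the host alone
(`frozen_reference`); uniform formal charges are the fallback.

FMO2 re-solves close QM pairs (pair R_min ≤ 6 Å by default) as dimers in
the remaining embedding and decomposes the interaction PIEDA-style:

    ES = Σ_{a∈I, b∈J} γ_ab q_a q_b      (frozen monomer charges)
    EX = Σ A_ab e^(−r/ρ_ab)             DI = −Σ C6_ab/(r⁶ + r_damp⁶)
    CT = (E_IJ − E_I − E_J) − ES − EX − DI

CT is a remainder and therefore absorbs mutual polarization — a coarser
split than formal PIEDA. Distant pairs (and any pair touching an MM
fragment) keep the ES term only. Dimers are cold-started from uniform
charges: a warm start from the frozen monomers can land on a different
integer-occupation branch than a direct solve of the same atoms, which
would break the exact limits below.

Total energies assemble from *internal* energies (the external-field term
stripped from each monomer/dimer), which avoids double-counting the
embedding electrostatics: with one fragment, or two fragments plus their
dimer, the assembly telescopes to the whole-system energy exactly
(measured ≤ 2×10⁻¹⁵ relative over 200 fixtures); with three or more
fragments the neglected many-body terms stay below 2 kcal/mol on 12-atom
test clusters. Binding energies are vertical, fixed-geometry differences
E(complex) − E(host) − E(guest) with the guest always all-QM; no MM–MM
relaxation enters (intra-MM terms cancel between complex and host).

## Descriptors and region selection

The shift profile joins apo and holo runs by fragment id (guest excluded —
it has no apo state) and sorts by R_min. The convergence radius is, in
strict mode, the smallest sampled R such that every fragment beyond R has
|Δε| ≤ δ; equivalently the largest offending R_min, or 0 if none offends.
It is non-increasing in δ and invariant to row order. A quantile mode
replaces the hard maximum with a tail quantile for outlier-tolerant use.
δ defaults to 0.01 eV — roughly the engine's outer-shell response scale
and well above its convergence noise; real studies should set δ from their
own profile's noise floor. Boundary equality is inclusive (R_min ≤ R_conv).

The short-range selector implements cutoff ∪ interaction-threshold
(defaults 5 Å, 2 kcal/mol, absolute value of the pair total); the union is
the conservative reading of the conventional rule, and an `intersect`
flag provides the conjunctive variant. Empirical regions require an
explicit fragment list. All regions always include the guest.

## The charge-flow network

Edges come from dimer charge shifts: δq_I > 0 means fragment I lost
electron density to its partner, drawn as I→J with weight |δq_I|, kept
when the weight exceeds 0.005 e (default). "Hub" is defined operationally
as a mediation-triplet participant: k is a hub for (i, k, j) when edges
i–k and k–j exist but i–j does not; nodes are ranked by triplet count,
then betweenness centrality (networkx, normalized), ties by id. Both
scores are reported, and the triplet predicate is checked exhaustively in
the tests.

## Synthetic generators

All generators are pure functions of (parameters, seed).

- **Planted-decay profiles**: R_i ~ U(0, r_max], Δε_i = ±A e^(−R_i/λ) + η,
  η ~ N(0, σ²); the analytic crossover λ ln(A/δ) is stored as truth.
  Default r_max = 25 Å matches the R_min span of protein- or
  framework-sized hosts.
- **Planted-hub networks**: hub–spoke stars with super-threshold weights;
  spoke–spoke edges are never drawn and noise edges form a matching on
  leftover nodes, so planted hubs are exactly the mediation participants.
- **Host–guest complexes**: three concentric shells (cavity radius 4.5 Å,
  +2.5, +5) of randomly oriented 4-atom Si/O tetrahedral clusters around a
  neutral but strongly polar O/H guest displaced 1 Å off-center — a
  hydrogen-bonding ligand bound to one side of a framework pocket. A
  cationic guest (the zeolite template case) is one parameter away but is
  not the default: its hole delocalizes over the quasi-degenerate host
  band, which the integer-occupation engine cannot converge.
- **Cluster assemblies**: replicas of one closed-shell, well-gapped 4-atom
  composition at non-overlapping sites; the fixture class for the FMO
  exactness identities (gap ≥ 1.8 eV keeps the SCC cycle safely inside one
  occupation branch).

What the generators do *not* emulate: covalent host–guest boundaries (no
link atoms — severed bonds simply lose their hopping terms), solvent,
conformational ensembles, and realistic protein/zeolite topology. Passing
tests therefore demonstrate the *protocol logic* — descriptor extraction,
radius detection, region comparison — not chemical accuracy for real
systems.

## Observed behavior of the toy pipeline

On the default complexes the strongest |Δε| sits in the guest-contact
shell and |Δε| decreases with R_min in the rank sense in ≥ 90% of seeds,
but the *single closest* fragment carries the single largest shift only
about half the time: the gap response factor varies severalfold with
fragment orientation, and repolarization makes next-shell shifts
comparable — the nonlocal propagation the descriptors exist to expose.
Mean |E_bind(region) − E_bind(all-QM)| falls monotonically through nested
radii (≈0.03 → ≈0.001 → 0 kcal/mol at cavity+1 Å, +3 Å, ∞ over 20 seeds).

Strict-mode radius detection recovers the noiseless planted crossover to
within one grid spacing, but under noise its "last offender" statistic is
intrinsically boundary-sensitive: near the crossover the signal sits at δ,
so noise of σ = δ/5 pushes a third of just-beyond rows over threshold, and
with uniform random sampling the gap from the crossover to the nearest
sample is exponentially distributed, exceeding twice the median spacing in
a quarter of profiles even at σ = 0. Recovery within 2× median spacing is
therefore ~30% under the benchmark ensemble (A ∈ [0.1, 1] eV, λ ∈ [1, 4] Å,
σ ≤ δ/5, n = 500, r_max = 25 Å), not a high-nines rate; the quantile mode
exists precisely to trade this boundary sensitivity for robustness.

## Determinism

Fragment sweeps are ordered by id, eigen-decompositions are deterministic,
generators derive everything from their seed, and emitted TSV/JSON use
fixed float formats (shift profiles at full precision so the delta-column
invariant survives a round trip); identical inputs give byte-identical
outputs, which the manifest checksums make checkable.
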