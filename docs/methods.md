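# Methods

## Scope and model

The package studies conformational cycling of RecA/RadA-like helical
filaments at desk scale. Instead of a solvated all-atom system it uses a
coarse-grained bead model (one bead per backbone atom N, Cα, C′, uniform
mass 110 g/mol) governed by an elastic network, and drives transitions with
the standard targeted-MD (TMD) restraint. The analysis layer — per-residue
dihedral winding (CCDA) and rotary/zero-rotary classification — is the same
computation one would apply to an all-atom trajectory; only the dynamics
engine is a scaled-down stand-in.

## Targeted-MD restraint

The restraint energy is

    U_TMD = (K / 2N) · (RMSD(t) − RMSD0(t))²

with K the force constant in kcal·mol⁻¹·Å⁻² (default 200, the value used by
the published filament protocol), N the number of restrained atoms and
RMSD(t) the *best-fit* RMSD of the current coordinates to the target over
the restrained selection (Cα by default; configurable to all backbone
atoms). The K/2N prefactor is the NAMD TMD convention; it keeps the energy
per system independent of selection size. RMSD0(t) is a linear schedule
from the current RMSD down to zero, clamped at zero once reached.

Forces use the analytic gradient of the fitted RMSD,
g_i = (x_i − y′_i)/(N·RMSD) with y′ the target superposed onto the mobile
coordinates; the optimal rotation/translation are stationary, so their
dependence on x contributes nothing (envelope theorem). At RMSD below 1e−8 Å
the gradient is defined as zero: the fitted RMSD is non-differentiable at
its minimum and the restraint force vanishes there whenever RMSD0 = RMSD.
Superposition is the determinant-corrected least-squares rigid fit
(Kabsch/quaternion family, via `scipy.spatial.transform.Rotation`); only
proper rotations are returned, so mirror images keep a nonzero RMSD — this
is what lets the restraint distinguish left- from right-handed filaments,
whose inter-bead distance matrices are identical.

## Elastic network and its morphing variant

Springs connect all bead pairs within a 10 Å cutoff of a reference
structure, with rest lengths equal to the reference distances and
k = 1 kcal·mol⁻¹·Å⁻² (classic Cα-ENM values). For a single transition leg
(`run_tmd_leg`) the network is static.

For the four-leg cycle (`run_cycle`) a single-basin network anchored at the
start state proved unusable: at deformations of several Å the network
becomes frustrated and traps the chain 1.5–2 Å from every target, a plateau
that does not shrink with longer legs. The cycle driver therefore uses a
mixed-basin variant: connectivity is fixed by the initial state, but during
each leg the rest lengths interpolate linearly from the distances of the
leg's start configuration to those of the leg target. The *reported*
potential is the deformation energy of each frame evaluated under the
initial-state network, zero-referenced to the initial state (exactly 0 at
t = 0). This quantity rises as the filament leaves the initial
conformation, peaks mid-cycle and returns near zero on closure, giving the
familiar barrier-shaped profile; per-leg summaries report start/end/max and
barrier height (max − start), flagging the leg holding the global maximum.
Barrier values are properties of the toy model and are reported
qualitatively (the first leg, leaving the initial basin, carries the
largest barrier); they are not comparable to all-atom energies.

## Integrator and units

Langevin dynamics with the BAOAB splitting; defaults dt = 10 fs, friction
1 ps⁻¹. Internal units are Å, ps and kcal/mol (acceleration conversion
418.4 Å·ps⁻² per (kcal·mol⁻¹·Å⁻¹)/(g·mol⁻¹)); reported times are ns. All
noise comes from one `numpy` PCG64 generator per leg, seeded from the run
seed, so trajectories are bitwise reproducible on one platform. Runs abort
with the offending frame index if energies go non-finite or any coordinate
exceeds 10⁶ Å.

The default temperature is an *effective* 70 K rather than the 310 K of the
all-atom protocol the engine stands in for. The elastic network is a
potential of mean force with kcal-scale spring constants; sampling it at
310 K produces thermal Cα fluctuations of ~0.8 Å (measured on the standard
12-residue filament), which would drown the sub-Å resolution needed to
decide whether a leg reached its target. 70 K keeps thermal Cα RMSD near
0.3 Å while leaving the dynamics stochastic. Each leg's RMSD0 schedule
reaches zero at 75% of the leg and holds there, so the system settles
before end-of-leg measurements.

## Study conditions (defaults)

| parameter | value | notes |
|---|---|---|
| filament | 12 residues, rise 3.8 Å, twist ±100°, radius 2.3 Å | backbone-decorated |
| quartet | left-handed / ring-like arc / intermediate twist / right-handed | pairwise fitted Cα RMSD > 1 Å enforced |
| K | 200 kcal·mol⁻¹·Å⁻² | published TMD force constant |
| ENM | cutoff 10 Å, k 1 kcal·mol⁻¹·Å⁻² | classic Cα-ENM scale |
| leg | 3000 steps × 10 fs (30 ps), stride 25 | 4 legs ≈ seconds on one CPU |
| temperature | 70 K effective | see above |

The filament length is chosen so that K = 200 with N = 12 restrained Cα
beads yields a per-atom restraint stiffness (≈ K/N²) able to track the
schedule against the network; much longer filaments dilute the restraint
(its per-atom stiffness falls off as 1/N²) and would need a larger K than
the published one.

## Dihedrals, unwinding and CCDA

φ and ψ are signed torsions in (−180°, 180°] under the IUPAC convention
(cis = 0°). A residue's φ needs the previous residue's C′ and ψ the next
residue's N, so the first residue has no φ and the last no ψ; such entries
are explicit NaN markers, never zeros, and `classify_rotary` refuses to
classify them unless told to skip. Unwinding maps each per-frame step into
(−180°, 180°] and accumulates; it is exact provided per-frame steps stay
below 180°, which constrains trajectory output strides. CCDA is
360° × |round(net winding)|: the *net* (signed) number of full turns,
reported as a magnitude. Net winding — rather than accumulated absolute
path length — is the only reading under which the reference linker values
quantize to multiples of 360°. A half-turn excursion (±180°) therefore
rounds to zero; transient rattling does not count, only completed turns.
Classification uses exact zero winding (winding numbers are integers by
construction), partitioning the analysed region into zero-rotary (both
angles zero) and rotary residues.

The bundled linker reference table (residues 71–88) classifies into 5
zero-rotary residues (I71, K74, E82, R83, K88) and 13 rotary residues under
this rule. Two of the 13 (F73, with one φ turn, and N85, with one ψ turn)
sit outside the narrower 11-residue rotary list sometimes quoted for this
region; no published rule distinguishes them from other single-turn
residues, so this package reports every nonzero-CCDA residue as rotary
rather than guessing a further criterion.

## Synthetic generators and what they do (not) show

Filaments are ideal helices (Cα exactly on the helix; twist sign sets
handedness), optionally decorated with N/C′ beads placed in the local frame
of the Cα curve at idealized bond lengths so φ/ψ are defined everywhere.
Programmed-rotation trajectories are rebuilt frame-by-frame from internal
coordinates (NeRF placement; idealized peptide geometry N–Cα 1.46 Å,
Cα–C′ 1.52 Å, C′–N 1.33 Å, angles 111–121.7°, ω = 180°): each programmed
torsion advances linearly to w·360° with Gaussian jitter applied *in
dihedral space*, so the ground-truth winding stays exact no matter the
noise draw (for noise s.d. ≤ 20° and feasible step sizes). Passing the
recovery tests therefore shows the unwinding/CCDA chain is exact on its
own terms; it does not show robustness to missing frames, stride aliasing
(steps ≥ 180°), or correlated backbone motion of real trajectories. The toy
filaments likewise share nothing with real RadA geometry beyond
handedness/twist/rise bookkeeping — protomer interfaces, ATP sites and
sequence effects are absent, so engine results are method demonstrations,
not statements about RadA energetics.

## Sequence identity

`percent_identity` is a global (Needleman–Wunsch) alignment via
`Bio.Align.PairwiseAligner` with match +1, mismatch 0, linear gap −1;
identity = matches / alignment columns × 100. The scoring is deliberately
transparent rather than tuned; the only exact reference point is the
degenerate case — the right- and left-handed filament end states are
conformations of the same protein, so their identity is 100% regardless of
scoring. The bundled state FASTA is a synthetic stand-in pair (identical
records, as the degenerate case requires); identities between *different*
homologs depend on the aligner and scoring used and are not reproduced
here.

## Numerical choices and edge cases

- PDB I/O is fixed-column; coordinates round-trip to 1e−3 Å (3 decimals),
  residue ids exactly. Malformed records raise errors carrying the line
  number; multi-MODEL files become trajectories (frame times default to
  the model index in ns, since PDB stores no times).
- Superposition requires ≥ 3 non-collinear atoms per side; collinear
  selections (e.g. a radius-0 filament) are rejected rather than silently
  fit.
- `build_elastic_network` warns (with the atom list) if any atom has no
  spring.
- Degenerate schedules: `rmsd0_linear_schedule` rejects negative initial
  RMSD and non-positive durations; restraint evaluation outside the
  schedule domain is an error.
- The rigid (steps = 0) pipeline mode replays the initial state so that
  downstream analyses (all-zero CCDA table, empty rotary list, zero energy
  profile) remain well defined.

## Known limitations

Energetics are qualitative only: the network has no excluded volume, no
sequence specificity and no solvent, and the morphing rest lengths remove
most of the true transition frustration by construction. CCDA event *times*
(when each winding increment completes) are simulation-specific and not a
stable output of the toy model. The percent-identity utility is pairwise
only — no multiple alignment.
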