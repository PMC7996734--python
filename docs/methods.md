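# Methods

## Model overview

`alikin` treats an alignment of homologous RNAs as a single folding
problem over alignment columns. A consensus secondary structure is a
non-crossing set of column pairs; its score is the *pseudo free energy*

    ΔG#(s) = ΔḠ(s) + λ · Σ_{(i,j) ∈ s} C_ij
    C_ij   = V_ij − φ · Q_ij

* **ΔḠ** — mean over rows of the nearest-neighbour free energy of the
  structure projected onto that row. Projection maps columns to ungapped
  positions and drops pairs that touch a gap or are invalid for the row
  (their inconsistency is already penalised through Q). Projected
  structures may therefore contain lonely pairs or short hairpins; the
  energy backends price them as-is (hairpins below the tabulated minimum
  use the smallest tabulated size).
* **V_ij** — conservation/covariation score: over all row pairs (k, l)
  whose bases at columns (i, j) both form valid pairs
  (AU/UA/GC/CG/GU/UG), the Hamming distance between the two rows' pairs,
  h(s_ik, s_il) + h(s_jk, s_jl). A compensatory exchange (G-C vs A-U)
  contributes 2, a consistent single mutation (G-C vs G-U) contributes 1,
  identity 0. V is defined so that it measures *difference between
  rows*, the covariation signal proper.
* **Q_ij** — fraction of rows that neither pair (i, j) nor are gapped at
  both columns.
* **Defaults**: λ = −1.0 kcal/mol per score unit, so covariation lowers
  the pseudo energy; φ = 1.0; V normalised by 1/M (`per_M`). Because a
  1/M prefactor on a sum over M(M−1)/2 row pairs does not average over
  row pairs, a `per_pairs` normalisation (2/(M(M−1))) is provided as an
  option. All three are CLI-exposed (`--lambda`, `--phi`, `--norm`).

With M = 1 the covariance sum is empty and the method degenerates
exactly to single-sequence folding.

## Energy backends

Two interchangeable loop-resolved backends implement the
nearest-neighbour model (hairpin / stack / bulge / internal / multiloop /
external contexts; no dangling ends or coaxial stacking, which keeps the
loop decomposition of a structure unique and unambiguous):

* **toy** — constant costs (stack −2.0, hairpin closure +3.0,
  bulge/internal +2.0, multiloop +4.0, external 0.0 kcal/mol). Every
  energy in the test suite is a short hand sum; all oracle-backed tests
  use this backend.
* **turner** — a compact Turner-style table bundled as plain text
  (`data/nn_params.txt`): pair/pair stacking at 37 °C, loop-size
  initiation with Jacobson–Stockmayer extrapolation beyond the table,
  affine multiloops. It is the production default and deliberately
  minimal: no tetraloop bonuses, no sequence-dependent internal-loop
  terms, single temperature.

## Hishape abstraction

A helix is a maximal run of directly stacked pairs; any interruption
(even a 1-nt bulge) starts a new helix. Its index is (i+j)/2 of the
innermost pair — a half-integer on 1-based coordinates — marked `m`, `b`
or `i` by the loop it closes; hairpin helices are unmarked. Levels keep:
`a` all helices, `m` hairpin + multiloop helices, `h` hairpin helices
only. Level `h+` keeps multiloop helices whose multiloop directly
contains ≥ 2 branches; since canonical multiloops always do, `h+`
coincides with `m` here, and a documented `hplus_as_m` flag records the
identification. Indices are ordered 5'→3' by helix opening position.
Markers participate in hishape equality wherever they are retained. The
open chain is the distinguished hishape `[_]`.

Alignment gaps shift helix indices between consensus and individual
coordinates; `project_hishape` recomputes indices through a row's
column→position map (an index over columns (25,29) with two upstream
gaps becomes 25 in sequence coordinates).

## Folding space and k-best classes

Canonical structures only: hairpins ≥ 3 unpaired bases, helices ≥ 2
pairs (no lonely pairs), every pair supported by a fraction ≥ 0.5 of
rows (`-f`). The space is enumerated exhaustively by a non-ambiguous
interval recursion — at the target scale of a few tens of columns this
is exact and fast, so no banded or DP search is needed; the contract is
simply "identical to exhaustive enumeration + classification", and an
independently coded backtracking oracle verifies it in the tests.
Classes are ranked by class-minimum pseudo energy; ties between classes
break on the rendered hishape text and ties within a class on the
representative's dot-bracket string, making every output byte-identical
across runs.

The `-x e` filter removes structures containing an external-loop
component (a maximal substructure rooted in the external loop) with
pseudo energy strictly greater than `e`; with `e = 0` exactly the
positive-energy components are excluded.

## Refolding pathways

Moves add or remove one base pair unique to start or target, so a path
between structures at base-pair distance d has exactly d+1 states; no
move can create a hairpin < 3 when the endpoints are canonical. The
heuristic keeps a frontier of at most `width` (default 16) partial
paths, advanced one move per round and ranked by **lowest
saddle-so-far** (then current energy, then dot-bracket text). Ranking by
the objective being minimised — rather than by current energy — is the
key design choice; both orderings fit a "keep the k best" scheme, and
the saddle ordering directly targets the barrier estimate. Frontiers
are deduplicated by state. Indirect routes a→m→b through intermediate
hishreps score max(leg1, leg2) and the best of direct + all
single-intermediate routes is returned; intermediates are the other
hishreps selected for simulation (single-level routing, no recursion).

On small single-sequence instances the complete direct move graph is
tractable, and a best-first minimax search over it supplies the exact
saddle; tests verify the heuristic reaches it at saturating width and
that the estimate is monotone non-increasing in width.

## Kinetics

Rates between hishreps follow Arrhenius:
`R[a][b] = A·exp(−(B_ab − E_a)/(R_gas·T))`, with R_gas = 0.0019872
kcal/(mol·K). Barriers are symmetrised to the best value found in
either direction, which enforces detailed balance with respect to the
Boltzmann distribution of the class pseudo energies. Defaults A = 1
(time in units of 1/A) and T = 310.15 K; both CLI-exposed. A pair found
disconnected is an explicit `None` (rate 0, warned); an absent barrier
is an error — never a silent zero.

The master equation dp/dt = pR is integrated by symmetrised
eigendecomposition (S = D^{1/2} R D^{-1/2} with D = diag π is symmetric
under detailed balance), with the top eigenvalue pinned to exactly zero
so that populations remain accurate over arbitrarily many decades of
time; `scipy.linalg.expm` is the fallback for non-detailed-balance
input. The stationary distribution is computed independently by a
linear solve of πR = 0 with normalisation and serves as a cross-check
of the long-time limit. Output times default to 60 log-spaced points in
[1e−2, 1e10]. The default protocol simulates the selected hishapes plus
the open chain, starting with all population in the open chain; the
`--neg-only` preset restricts the states to strictly negative level-h
hishapes (plus the open chain).

## Synthetic data

The generator plants a known structure in a reference sequence and
derives M rows independently: each planted pair is jointly replaced by
another valid pair type with probability `comp_rate` (default 0.7 — a
strongly covarying family), unpaired positions mutate at `mut_rate`
(default 0.1), and gaps enter per row at `gap_rate` (default 0.0;
`terminal` policy gaps only contiguous unpaired terminal runs so planted
pairs stay intact, `interior` gaps any unpaired position). Generation
is reproducible from `seed`.

What it emulates: the covariation/conservation signal the pseudo energy
rewards, coordinate shifts from gaps. What it does not: phylogenetic
correlation between rows, indel processes at paired sites, alignment
errors. Passing the recovery tests therefore shows the scoring machinery
extracts a planted signal, not that real alignments of any quality will
yield correct consensus structures.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by design: alignments
of ≤ 30 columns and ≤ 8 rows, path fixtures of ≤ 17 nt, k ≤ 8 —
sizes where the exhaustive oracles are exact, so every comparison is
against ground truth rather than against a second heuristic.
Tolerances: rate-matrix row sums 1e−12; population conservation 1e−8;
equilibrium agreement 1e−6; float-sum order inside the evaluator is
fixed (sorted pairs) so equal structures always receive bit-identical
energies, which the deterministic tie-breaking relies on.

## Known limitations

* Exhaustive enumeration scales exponentially with pairable columns; the
  guard raises rather than degrading silently. A classified k-best DP
  would be the natural optimisation and can sit behind the same
  contract.
* Pseudoknots, dangling ends, coaxial stacking and co-transcriptional
  folding are out of scope.
* Class populations are attached entirely to hishreps; class ensemble
  (partition-function) energies are not modelled.
* The indirect-pathway search uses single intermediates only.
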