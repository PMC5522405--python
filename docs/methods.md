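# Methods

## Descriptors

**Chain vectors and roles.** A triolein is reduced to three vectors from
its central glycerol site to per-chain reference points: the unweighted
midpoint of the two C=C carbons in atomistic frames (both atoms are
carbon, so the midpoint is their centre of mass), or the D-bead in the
12-bead-per-lipid coarse-grained mapping (GLY centre, ES1–ES3 ester beads,
and C/D/C beads per oleoyl chain). Roles are assigned by scalar projection
on the protein's N→C axis: largest projection → sn1, smallest → sn2,
remainder → sn3; exact ties go to the lower raw chain index. Roles are
re-assigned every frame by default because the swing chain genuinely
changes identity over time; a frame-0 locking flag exists for sensitivity
checks. The axis is the normalised vector between the C- and N-terminal
barrel COMs for real structures, or the generator's declared axis for
synthetic frames.

**Orientation and conformation classes.** Orientation uses sn1-sn3 only:
head-to-legs below 75°, legs-to-head in [105°, 180°], random between. The
two boundary angles fall in the random band so the three classes partition
[0°, 180°] exactly. Conformation thresholds (acute ≤ 60°, obtuse ≥ 105°)
were chosen to separate the observed signature peaks — ≈30° acute peaks of
fork and trident states, the 75–85° random band, and 135–150° fork obtuse
peaks — with maximal margins; both are configurable. Tuning fork and chair
are deliberately not distinguished (one FORK_LIKE class): both have two
chains on one side of the glycerol and no angle criterion in this
descriptor set separates them. A TG pair is random whenever either TG is
individually random; otherwise the four head/legs combinations map to
parallel N-N / antiparallel N-C / parallel C-C / antiparallel C-N.

**Bend and twist.** Bending is the angle between the vectors m (central
β-sheet COM → N-barrel COM) and n (central β-sheet COM → C-barrel COM).
Twist is the signed angle between the perpendicular components of the two
barrel COMs about the protein axis (the line between the central sheet's
N-end and C-end sub-range COMs), measured with the right-hand rule about
the N→C direction; this makes crystal-like twisting positive and
untwisting negative, matching the reported sign semantics. When both
barrels lie exactly on the axis the structure is collinear and twist is
returned as 0 by convention; one on-axis barrel is a degeneracy error
because its plane is undefined. Domain residue ranges are mandatory
configuration: the boundaries actually used for published bend/twist
values were never printed, so the shipped 2OBD-based defaults are marked
user-verifiable and the 139°/8° crystal values are treated as
construction anchors (exactly recoverable from synthetic scaffolds), not
as reproducible targets for real structures.

**RMSD and averages.** Superposition uses the SVD Kabsch solution
restricted to proper rotations; the test suite cross-checks it against an
independent Horn quaternion-eigenvalue implementation. The trajectory
average superposes each window frame onto the window's first frame before
taking per-site means (Cα selection recommended for proteins); an
iterative mean-reference mode is available behind a flag.

**Contacts.** A contact is an unordered protein-site/lipid-site pair with
Euclidean distance ≤ cutoff (default 5 Å); "site" means heavy atom in
atomistic frames (united-atom data carry no apolar hydrogens) and bead in
CG frames. Counting uses a k-d tree but is defined — and tested — as
exactly the exhaustive double loop. Residue-level sets are evaluated on a
time-averaged structure by default (any-site criterion), with a per-frame
occupancy mode (≥ 50% of frames) for robustness. Comparisons report both
percent-change conventions, 100·Δ/n_ref and 100·Δ/n_query, because both
appear in the literature for these systems; no single intent is guessed.
Distances are never minimum-imaged: inputs are assumed whole molecules,
and a bonded pair stretched beyond 10 Å raises a broken-molecule error
instead of being silently re-imaged. Hydrogen bonds use the standard
geometric criterion: donor–acceptor ≤ 3.5 Å and donor–H···acceptor angle
≥ 120°.

## Synthetic generator

The generator stands in for undeposited microsecond MD data; it emulates
the *statistical* structure of the bound-TG systems, not their physics.

Chain vectors are realized in a canonical frame — sn1 along the tunnel
axis, sn3 at the target sn1-sn3 angle in a fixed half-plane, sn2 placed at
the target sn2-sn3 angle beyond sn3 — then rotated by a seeded uniform
azimuth about the axis. Any target pair in [0°, 180°]² is realizable this
way (coplanar construction), and realized angles equal targets to ≈1e-14.
Legs-to-head orientations are the same geometry flipped 180° about a
perpendicular axis. Chain length defaults to 12 Å (central site to
double-bond midpoint of an oleoyl chain); the atomistic variant puts two
pseudo C=C carbons 0.7 Å apart straddling each tip.

Signature angles: tuning fork (30°, 135°), trident (30°, 30°), random
(75°, 85°) — the observed peak positions for tunnel-bound triolein; the
150° sn2-sn3 variant seen for the N-terminal TG in united-atom runs is
reachable by overriding the targets. Noise rotates each chain vector by
|N(0, σ)| degrees about a uniformly random perpendicular axis, hard
truncated at a configurable bound; this preserves chain lengths, and the
angle between two chains then changes by at most twice the bound. For
frames in the random orientation state the sn1-sn3 value is sampled from
the 76–104° band shrunk by twice the truncation bound (falling back to
the 90° band centre when the bound is large), so generator labels remain
consistent with the realized angles whenever the noise bound itself is —
that consistency is what makes the 100%-accuracy recovery tests
meaningful. With the default 20° truncation the head states keep a 5°
guard to the 75° threshold (30 + 2·20 = 70), while legs states keep a 10°
guard to 105° only for truncations ≤ 15°; tests choose margins per state.

Pair states map to per-TG orientations as parallel N-N = (head, head),
antiparallel N-C = (head, legs), parallel C-C = (legs, legs), antiparallel
C-N = (legs, head); the random pair samples which single TG sits in the
random band. State sequences are explicit or Markov: chains start from
their stationary distribution (left Perron eigenvector) so empirical
frequencies are unbiased at any length. Two TGs sit at the quarter and
three-quarter points of a 60 Å tunnel axis — the tunnel length of the
crystal structure — giving 30 Å between central sites.

Scaffolds realize a bend θ and twist θₜ exactly through COM placement:
with the axis along x and barrels at polar angle γ from it,
sin²γ = (1 + cos θ)/(1 + cos θₜ), realizable whenever θ ≥ |θₜ|. Each
domain is a small rigid Gaussian point cloud whose offsets are re-centred
so its COM lands exactly on the prescribed point. A fully straight
scaffold (θ = 180°) necessarily places both barrels on the axis; it is
allowed only with θₜ = 0 and relies on the collinear-twist-is-zero
convention.

What the generator does *not* emulate: excluded volume and packing against
tunnel walls, realistic lipid internal geometry (55 heavy atoms reduced to
10 sites), force-field energetics, and temporal correlation of the noise.
Passing tests therefore demonstrate correctness of the descriptors and
classifiers under known ground truth — not that real TG-bound CETP
behaves this way.

## Numerical choices and problem sizes

All internal units are Å and degrees; GRO input (nm) is converted on
read. Angles use arccos of the clipped normalised dot product; signed
twist uses atan2, so no precision is lost near 0°/180°. Histograms are
probability mass (sum exactly 1) over half-open bins with the last bin
closed at 180°. Chains shorter than 0.1 Å, coincident domain COMs
(< 1e-6 Å) and on-axis barrels (< 1e-6 Å perpendicular distance) are
degeneracy errors rather than NaNs. Sites with unrecognisable element
prefixes (all CG bead names) get mass 0, which forces geometric COM
weighting for any selection containing them; the fallback is logged,
never silent.

Default analysis sizes keep every stage at desk scale: 10,000-frame
classification runs (seconds to tens of seconds), 5,000-frame analysis
trajectories, 100 random instances for contact-oracle equivalence, 7×7
bend/twist recovery grids. The xyzcsv dialect writes floats with %.17g
and reads with round-trip parsing, so trajectory round-trips are
bit-exact.

## Known limitations

- Insertion-code PDBs are rejected rather than renumbered; renumber
  upstream if needed.
- No xtc/dcd readers; convert binary trajectories to multi-model PDB or
  xyzcsv first.
- The classifier is memoryless; no hidden-Markov smoothing of label
  sequences and no kinetic rate estimation.
- Secondary-structure assignment, tunnel-length measurement and
  free-energy decomposition are out of scope; external tools' outputs can
  be ingested as tables where relevant.
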