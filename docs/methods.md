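# Methods

## The site-moiety map model

A site-moiety map (SiMMap) summarises how an ensemble of docked
compounds engages a binding site. Its unit is the **anchor**: a group
of spatially adjacent site residues that interact with docked compounds
significantly more often than chance, typed by the dominant interaction
— electrostatic (E), hydrogen bond (H), van der Waals (V), or combined
EH — together with a frequency-ranked list of the ligand moieties seen
at those contacts. The model assumes that the docked poses, whatever
engine produced them, are placed plausibly enough that contact
*frequency* across thousands of compounds is informative even where any
single pose is noisy.

The pipeline, in order:

1. **Pocket definition.** The catalytic site is every residue with at
   least one heavy atom within `cutoff_angstrom` (default 8.0 Å,
   boundary inclusive) of a bound reference ligand supplied in the same
   coordinate frame. Heavy atoms only: crystal structures usually lack
   hydrogens, so an all-atom rule would measure deposition practice,
   not geometry. Structural superposition of the reference ligand into
   the target frame is deliberately out of scope — the user supplies a
   positioned ligand. Waters and non-reference HETATM groups are
   excluded; metals are carried only as annotations.

2. **Interaction detection.** Docking engines classify contacts with
   internal energy terms that are not portable; we re-detect E/H/V from
   geometry so any engine's poses can be used:
   * H: donor–acceptor heavy-atom distance ≤ 3.5 Å; when the ligand
     donor carries explicit hydrogens the D–H…A angle must be ≥ 120°,
     otherwise distance-only.
   * E: oppositely charged groups with closest heavy-atom distance
     ≤ 4.0 Å. Charged groups are formal charges plus the standard
     physiological-pH ionisations (carboxylate, sulfonate, phosphate,
     aliphatic amine, guanidinium) and the Lys/Arg/His/Asp/Glu side
     chains. Histidine is donor, acceptor and positively chargeable,
     so the same residue can anchor both E and H contacts.
   * V: any heavy-atom pair within (r_vdw,i + r_vdw,j + 0.5 Å), capped
     at 4.5 Å, excluding pairs already credited to H or E.
   These are standard structural-biology cutoffs; all are exposed in
   `InteractionRules` / YAML config. Contacts roll up to at most one
   record per (residue, type) per compound; E and H may co-occur.
   Each record is labelled with the moiety of the ligand fragment at
   the contact (contact atoms plus one-bond neighbours, matched against
   the catalog; the best-covering, most specific group wins).

3. **Profiles and the shuffle null.** For each type, an N × R binary
   matrix M(I) records compound-residue contacts, built from the
   `top_k` compounds by docking score (default 2,000; lowest energy,
   ties by id). The observed per-residue frequency f_j is standardised
   against a permutation null: each of `n_shuffles` (default 1,000)
   replicates permutes every row independently, preserving each
   compound's contact count — the null keeps every compound exactly as
   "sticky" as observed but scatters *where* it sticks. μ_j and σ_j
   are the mean and population SD of the shuffled column frequencies
   and Z_j = (f_j − μ_j)/σ_j. Residues with Z_j ≥ 1.645 (one-sided
   95%) are consensus residues. Whole-matrix shuffling was considered
   and rejected as the default because it also randomises compound
   stickiness, making promiscuous libraries look artificially
   significant. Shuffling is vectorised (argsort of uniform keys,
   chunked over replicates) and fully determined by the seed.
   If σ_j = 0 (permutation-invariant column, e.g. R = 1 or an all-ones
   matrix), Z_j is +∞ when f_j exceeds μ_j beyond numerical noise and
   0 otherwise, and the statistic is flagged degenerate.

4. **Anchor grouping.** Within each type, significant residues are
   single-linkage clustered on their mean contact points with a
   `link_distance` of 3.5 Å; each cluster is an anchor with centroid =
   mean contact point. An E anchor and an H anchor merge into an EH
   anchor when they share a residue or their centroids lie within
   `link_distance`. The grouping algorithm and both thresholds are this
   package's design (the anchor concept does not prescribe one);
   single linkage was chosen because contact clouds are small and
   elongated, and the merge rule reproduces the expected behaviour of
   doubly-competent residues such as histidine pairs. Anchors are
   named type + rank by descending member count (cosmetic only).

5. **Moiety preferences.** An anchor's preference for moiety m is the
   fraction of profile compounds with ≥ 1 record of the anchor's
   type(s) at an anchor residue labelled m; descending, ties
   alphabetical.

6. **Scoring and ranking.** For a new compound x with docking score
   E(x) and heavy-atom count M,

       S(x) = Σ_a AS_a(x) + (−0.001) · E(x) / M^0.5

   with AS_a = 1 if the compound has ≥ 1 contact of the anchor's type
   with ≥ 1 anchor residue, else 0; for EH anchors a hydrogen-bond-only
   match earns 0.5, while any electrostatic contact earns the full 1
   (the half-credit rule is stated only for hydrogen bonds; we resolve
   the ambiguity in favour of full credit for the stronger contact).
   √M damps the size bias of raw docking energies. The match predicate
   ("≥ 1 anchor residue") is the permissive reading; a stricter
   majority-of-residues mode is available in config. Ranking is by
   descending S, ties by lower E then id. Enrichment reports
   (#actives in top k)/k for both SiMMap and docking rankings.

## Moiety fingerprints and clustering

The 90-bit moiety fingerprint marks presence/absence of 90 functional
groups in checkmol's spirit. The exact historical 90-group list is not
published alongside the method, so the shipped catalog
(`data/moiety_catalog_v1.yaml`, version `simmap-90.v1`) is this
package's reconstruction: an ordered, versioned table of SMARTS
patterns covering the classical functional groups (carbonyl family,
alcohols/phenols/ethers, amines and other nitrogen groups, sulfur and
phosphorus acids and esters, halogens, ring/aromatic descriptors,
unsaturation). It is data, not code, and can be corrected by bumping
the version; bit-for-bit checkmol compatibility is a non-goal.

Compound similarity for novelty analysis uses 1 − Pearson r between
fingerprints as the distance, with hierarchical clustering under
centroid linkage. Centroid linkage requires coordinates, so the
linkage runs on the raw bit vectors; the Pearson distance matrix is
emitted separately for heatmap ordering. Centroid linkage can produce
inversions (non-monotone merge heights); the tree object counts them
rather than hiding them. Inputs are sorted by compound id before
linkage so merge order is reproducible.

Anchor conservation is the arithmetic mean (reported to one decimal)
of user-supplied per-residue grades on the ConSurf-style 1–9 scale;
the package consumes the table, it does not compute alignments.

## Synthetic fixtures

The generator builds a fully in-silico study system so every stage is
testable without docking software: pocket residues sit on icosahedron
vertices at 7.5 Å from the origin (inside the 8 Å rule), each a minimal
amino acid carrying exactly the chemistry its role needs — a
guanidinium (ARG) for E/EH, an amide (ASN) for H, a carbon cluster
(LEU) for V, alanine as inert background. Poses place small catalog
fragments radially: formate at 3.0 Å (E + H) or 3.8 Å (E only),
acetaldehyde at 3.0 Å (H), benzene tangential at 3.4 Å (V), with the
rest of each fragment pointing inward so only the intended residue is
touched; the ≥ 63° angular spacing keeps a fragment > 6 Å from every
other residue. Contacts are planted with probability `p_hot` at anchor
residues and `p_bg` elsewhere, and the generator returns the exact
intended (residue, type, moiety) sets, so with p_hot = 1, p_bg = 0
detection must recover the truth identically. Docking scores are drawn
from normal distributions, default mean −80, SD 10 **for binders and
decoys alike**, so that in screening experiments any enrichment can
only come from the anchor terms. A matrix-level generator
(`make_planted_profile`) plants hot columns directly for statistical
power studies, and `make_analog_families` plants fingerprint families
for clustering tests.

What the fixtures deliberately do not emulate: conformational
plausibility, force-field energies, correlated contacts between
neighbouring residues, pose errors that displace rather than delete
contacts, and score–structure correlation. Passing tests therefore
demonstrate the statistical machinery and the geometric rules, not
docking accuracy on real proteins.

## Default problem sizes

Tests and the acceptance script use desk-scale versions of the study
design: maps built from 60–200 synthetic compounds (instead of a
2,000-of-118,759 docking campaign), 300–1,000 shuffles, screens of 10
binders + 990 decoys over 50 seeds, and 100 replicates for the
planted-column power check. These sizes were chosen so the whole suite
runs in about a minute while keeping every statistical margin wide
(the planted effects sit ~15–20 null SDs from the mean, so scale-down
does not meaningfully reduce power).

## Numerical choices and edge cases

* σ estimates below 1e−7 are treated as exactly zero (cancellation
  guard in the streaming variance); the f_j > μ_j comparison in the
  degenerate branch uses a 1e−9 tolerance.
* Ties: top-k selection and ranking break ties lexicographically by
  compound id; moiety preferences alphabetically; anchor naming by
  pocket order.
* Altloc atoms keep the highest-occupancy conformer (ties by altloc
  letter).
* An empty pocket or an anchorless map is a warning, not an error;
  zero-heavy-atom poses and zero-variance fingerprints are errors.
* Every stochastic step derives its generator from one master seed
  (numpy `SeedSequence.spawn`), recorded in the map's provenance; the
  serialized map is byte-identical across reruns with the same seed.

## Known limitations

* Geometric E/H/V rules are a portable approximation, not a re-
  implementation of any docking engine's energy model; π–π and
  cation–π interactions, solvation, and explicit metal coordination
  are not modelled.
* The moiety catalog is a reconstruction; bit positions are stable
  only within a catalog version.
* Anchor grouping thresholds (3.5 Å, single linkage) are heuristic and
  site-size dependent; very large shallow sites may need a smaller
  link distance.
* Conservation grades are consumed, never computed.
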