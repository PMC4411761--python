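# Methods

## Molecular model and geometry

A structure is modelled as a union of balls: each atom is a ball of its van
der Waals radius r, represented as a weighted point with weight w = r².  The
power distance from a weighted point p to x is π_p(x) = ‖x − p‖² − w_p; it
vanishes exactly on the ball surface.  The regular (weighted Delaunay)
triangulation — the dual of the power diagram — is computed by lifting each
atom to 4D as (x, y, z, ‖x‖² − w) and taking the lower convex hull
(scipy/Qhull with the `Qt` option).  Atoms whose power cell is empty
("hidden" atoms) drop out of the lower hull and appear in no simplex, as
they should.  Numerically degenerate inputs are retried after a
deterministic joggle of magnitude 1e-8 Å with a fixed seed; exactly coplanar
inputs are rejected up front.

Every simplex carries an orthosphere — the sphere with zero power to all of
its weighted vertices (center constrained to the affine hull of the vertex
centers for dimension < 3).  Its squared radius is the simplex *size value*,
which may be negative where balls overlap deeply.  The *alpha value* of a
simplex is its entry time into the alpha-complex filtration: the size value
for unattached simplices, and the minimum coface alpha value for attached
ones (a simplex is attached when its orthocenter has negative power to a
vertex of a coface — the weighted Gabriel test).  At α = 0 the alpha complex
represents the space covered by the atoms; the complement of the alpha
complex represents the empty space.

### Size value vs. alpha value

The two quantities coincide for unattached simplices but can differ
arbitrarily for attached ones: an attached simplex inherits its coface's
entry time.  This matters at the molecular boundary, where sliver
tetrahedra — four nearly coplanar surface atoms — have empty orthospheres
bulging into the open exterior, with no bound on their radius.  Such a
sliver is "covered by balls" for any practical purpose, yet its alpha value
(and that of its attached facets) can be astronomically large.

The package therefore uses the two quantities for different jobs:

* **alpha value** decides *membership*: what is inside the alpha complex,
  what belongs to the complement, which hull triangles are open.  This is
  the filtration and it is monotone under the face relation.
* **size value** measures *width*: the local constriction a spherical probe
  must pass is the orthoradius of the crossed triangle itself, regardless
  of when that triangle happens to enter the filtration.  Edge widths and
  costs, bottleneck radii, the radius profile, and the ranking of mouth
  openings all use size values.  A probe cannot pass a covered triangle,
  whatever its entry time.

## Channel network

The dual graph of the complement has one node per complement tetrahedron
(positioned at its orthocenter) and one edge per complement triangle; by
filtration monotonicity a complement triangle's incident tetrahedra are
complement too.  Complement hull triangles are *mouths*; their incident
tetrahedra are boundary nodes, linked to a single EXTERIOR super-node.
Components not reachable from the exterior are voids and are pruned.  Edge
cost is length / width with the width floored at 1e-9 Å² (so sealed attached
crossings are effectively impassable); length is the distance between node
orthocenters, with no clamping of orthocenters that fall outside their
tetrahedron.  Node depth is the hop count from the boundary-node wave
front (an unweighted BFS).

## Endpoints

*Active sites.*  Each site atom (from a user residue list or a HETATM
ligand) votes for its nearest network node; the deepest of those nodes wins,
with ties broken by larger node width, then lower tetrahedron id.  This
per-atom voting beats snapping to the site centroid for large ligands.

*Mouth representatives.*  Mouths are connected components (shared hull
edges) of open hull triangles.  The number of mouths is scanned over the
distinct positive triangle *widths* (size values): the reported α_max is the
smallest level maximizing the component count.  Each component is
represented by its widest **centered** triangle — one whose orthocenter lies
inside the triangle, so that the orthosphere actually sits in the opening.
Sliver triangles are never centered (their orthocenters diverge sideways),
and a component with no centered triangle is a boundary-sliver artifact, not
a mouth, and is dropped.  The representative node is the incident
tetrahedron of that widest triangle; B_imp is the representative list sorted
by decreasing opening width and truncated to the user parameter k
(default 10).  The opening width doubles as the operational persistence of
the mouth — for unattached triangles it equals the length of the α-interval,
starting at 0, during which the opening exists in the complement.  This is
deliberately *not* the raw filtration entry time (see above) and not a full
persistence pairing either; it is the width-based proxy of the latter.

## Channels and pores

A channel is a minimum-cost walk between two endpoints (Dijkstra on the
interior network; paths may not shortcut through the EXTERIOR node).  Its
centerline is the polyline of path-tetrahedron orthocenters — the path
representation with nodes at the orthogonal-sphere centers of the top
simplices.  The shared triangles ride along: the bottleneck radius bn(x) is
the minimum triangle orthoradius over the path, i.e. the largest spherical
probe that traverses the channel.  Early designs also threaded the shared
triangles' orthocenters into the centerline; that was abandoned because the
orthocenter of a triangle with two near and one far vertex lies far off the
physical channel axis, which inflated arc lengths ~2.5× and destroyed the
straightness measure, while adding nothing (the triangle radii are still
sampled in the radius profile).

Iterated extraction yields edge-disjoint channels: after each round the
used edges' costs are raised to 1 + (sum of all original costs), which
exceeds the cost of any path of fresh edges; a round that still reuses a
saturated edge terminates the iteration.  The widest-path tree is the
maximum spanning tree under edge width; the tree path between any two nodes
attains the max–min width over all network paths, and pruning degree-1
non-important nodes reduces it to the union of pairwise paths between
important nodes.  Important pores are the shortest channels between all
pairs of the top-k mouth representatives, with exact-duplicate triangle
paths collapsed — no similarity-based filtering beyond that.

## Transmembrane pores

The membrane is a slab between two planes orthogonal to a unit normal
(default z, matching membrane-oriented input structures with planes at
z = ±h).  Mouth representatives project onto the normal into B_in / B_mem /
B_out; transmembrane pores connect B_in to B_out.  Each pore x is scored

    f(x) = (|x| / max|y| + bn(x) / max bn(y) + s(x)) / 3

over the transmembrane set.  The straightness s is computed on a uniform
arc-length resampling S of the centerline (default spacing 1 Å, the final
spacing adjusted so the last sample lands on the endpoint, at most 512
samples):

    s(S) = Σ_{d=1}^{⌊|S|/2⌋} Σ_{i=1}^{|S|−2d} d · cosθ(i, d) / Σ Σ d

where θ(i, d) is the *turning* angle between the chords S[i+d] − S[i] and
S[i+2d] − S[i+d].  With this convention a perfectly straight path scores
exactly +1 (the three-point angle at the middle vertex would give −1 for
straight paths, which would contradict straight pores being preferable, so
the turning-angle reading is used).  The outer limit ⌊|S|/2⌋ uses the floor
for odd |S|.

## Profiles and volume

Profiles are real functions on [0, d], d the channel length, parametrized
by centerline arc length.  The radius profile samples each path
tetrahedron's orthoradius at its centerline point and each crossing
triangle's orthoradius at the arc length midway between its flanking
tetrahedra; its minimum equals bn(x) (a simplex's face never has a larger
size value than the simplex, by the attachment rule).  Physico-chemical and
conservation profiles average the per-residue value of the four vertex atoms
of each path tetrahedron; residues missing from the scale/table are excluded
from the mean and an all-missing tetrahedron yields a NaN sample.  Shipped
scales: Kyte–Doolittle hydropathy, unit residue charge (Asp/Glu −1, Lys/Arg
+1, His +0.5), and Zimmerman bulkiness; all are editable TSV data files.
The electrostatic profile trilinearly interpolates a scalar grid (e.g. an
APBS OpenDX map; non-orthogonal grid axes are rejected) at the centerline
points, with a hard error naming any point outside the grid.

Channel volume is the empty volume of the path tetrahedra: per tetrahedron,
uniform Monte-Carlo samples (seeded, samples allocated proportionally to
tetrahedron volume, at least 50 per tetrahedron) estimate the fraction not
covered by any atom ball; the estimate and a binomial standard error are
reported.

## The synthetic tube generator

`make_tube` builds a ball arrangement whose ground truth is known by
construction: a straight channel of a given length and lumen radius along
z with a single constriction of known radius.  Design constraints that
shaped it:

* **Fine beads at the throat.**  For wall beads of radius r, a probe of
  radius ρ tangent to them has orthoradius √(ρ² + 2ρr) — the alpha-complex
  radius overestimates the probe radius by an r-dependent amount.  The
  aperture collar therefore uses beads of 0.25 Å, for which the orthoradius
  at a ρ = 2 Å throat is 2.236 Å, close to the probe radius; the rest of the
  wall uses vdW-scale beads (1.7 Å), whose chunkier tetrahedra keep the dual
  path smooth.
* **Golden-angle (helical) lattices on all passage surfaces.**  Stacked
  rings are exactly cocircular, which triangulates the lumen into "fans" of
  near-cospherical tetrahedra sharing one axis orthocenter; the dual path
  must walk around each fan, inflating arc length several-fold.  Helical
  placement has no cocircular subsets and yields straight dual chains.
* **An exactly convex outer shell.**  The outer boundary is a Fibonacci
  sphere of vdW-scale beads through the two rims, with polar caps removed.
  Over any rough open surface, boundary sliver tetrahedra have *unbounded*
  empty orthospheres (nothing outside the hull blocks them); placing the
  shell beads exactly on a convex sphere makes every shell hull facet a
  small sealed triangle, so those slivers end up behind sealed facets and
  are pruned as voids.  The only openings are the two polar mouths.
* **Irregular exact rim rings.**  A flat extremal ring at an open pole
  would again allow near-unbounded pole slivers; the rim rings carry an
  amplitude-modulated z-wave whose lobes bottom out at different depths,
  which caps pole slivers at the lobe scale.  The rims are exact
  (seed-independent); only interior lining/diaphragm beads receive the
  1e-3 Å degeneracy-breaking jitter, so the fixture's pole geometry is
  identical for every seed.
* **An hourglass constriction.**  Two conical funnels of mid-scale beads
  taper the wall to the fine throat collar; an abrupt wide-to-narrow step
  leaves a vestibule whose tetrahedra span wall-to-collar and zigzag the
  centerline.

With the defaults (length 40 Å, lumen 4 Å, constriction 2 Å) the structure
has ~2600 beads and analyses in a few seconds.  Across seeds the pipeline
reports exactly two mouths, one transmembrane pore with bottleneck radius
2.23 Å (grid-sampled inscribed radius 2.00 Å), centerline RMS deviation from
the construction axis ~0.07 Å, and straightness ~0.9996.

What the generator does *not* emulate: real vdW radius heterogeneity per
element, side-chain texture of channel walls, multiple competing pathways,
disordered loops at mouths, or solvent.  Passing on the tube shows the
machinery recovers constructed geometry; it does not validate biological
interpretation on real structures, where mouth ranking in particular will
face openings of comparable width.

`make_blob` (random cluster), `make_shell` (sealed cavity → pruned void)
and `make_barrel` (perforated slab) exercise triangulation, void pruning
and generic network properties; the barrel's flat faces deliberately retain
the boundary-sliver artifact and it is not used for ranking assertions.

## Numerical choices

* Attachment tolerance 1e-9 Å²; width floor 1e-9 Å²; hull facet lower-hull
  test at 1e-10 relative.
* Near-singular (sliver) orthosphere systems fall back to the minimum-norm
  pseudo-inverse solution rather than failing.
* Mouth-component ties in the α_max scan break toward the smallest level.
* active-site ties: higher depth, then larger node width, then lower id.
* Duplicate atom centers are dropped (with a warning) before triangulating;
  altloc handling keeps blank/'A' conformers; hydrogens and waters are
  excluded by default; HETATM atoms are kept aside for active-site seeding.
* The vdW table (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80, default
  1.70 Å) is total over element symbols and user-overridable; bottleneck
  radii shift by a comparable amount under a different table.

## Known limitations

* Persistence is operationalized as the opening width (size value), not a
  full persistence pairing; features that exist only at α > 0 levels are
  ranked by width, which can differ from their true lifetime.
* Boundary sliver tetrahedra remain in the network (they belong to the
  complement); their widths and positions are untrustworthy, but the
  size-based costs make them effectively unroutable and the centered-mouth
  rule keeps them out of B_imp.
* PDB round-trips re-derive radii from elements; bespoke per-atom radii
  (e.g. of synthetic structures) are not preserved by the format.
* Grid axes of electrostatic maps must be orthogonal.
* Channels are reported per endpoint pair without similarity clustering.
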