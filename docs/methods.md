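# Methods

This note records the models, algorithms and numerical conventions behind
pathviz, the defaults it ships with, and what its synthetic test surface
does and does not demonstrate.

## Coordinate model

Diagrams live in abstract canvas units with the SVG convention: origin at
the top-left, y growing downward, one unit = one CSS pixel at zoom 1.
Rectangles are stored as `(x, y, w, h)` with closed edges (`x .. x+w`
inclusive) so hit-testing at glyph borders is well defined. The `Rect` type
accepts zero extents — analysis hit bars legitimately have width 0 when
nothing was found — while diagram validation requires strictly positive
extents for canvases, glyph bounds and compartments.

A reaction edge consists of a backbone polyline, a reaction point (the
small square where the conversion happens), and participant connectors
ordered from the node toward the reaction centre. Connector polylines must
terminate within a tolerance ε of the backbone or the reaction point;
ε defaults to 0.5 canvas units and is configurable. SBGN conventions
constrain line endings: arrows only on outputs, circles only on
catalysts/activators, bars only on inhibitors.

## Subpathway highlight boxes

Each subpathway's box is the bounding rectangle of all backbone points,
connector points and participating node bounds of its member reactions,
grown by a padding (default 10 units) and clipped to the canvas. A
degenerate subpathway whose geometry collapses to a point gets a
2×padding square. Colours come from the profile's eight-colour
semi-transparent palette, assigned cyclically in sorted subpathway-id
order. The whole computation is a pure function of diagram + assignment +
profile: two runs serialize byte-identically, which is what lets a database
release precompute boxes once and serve them unchanged for the release
lifetime.

### Label placement

The placement container is the target box shrunk by an inner margin
(default 4 units). Obstacles are the other subpathway boxes' overlaps with
the container. The search enumerates **all maximal empty rectangles**:
every maximal empty rectangle is supported on each side by an obstacle edge
or the container boundary, so candidate vertical strips come from the
compressed x-coordinates; within a strip the free y-gaps give candidates,
and a pairwise-containment filter keeps the maximal ones. This is exact
(the test suite checks set equality against exhaustive grid enumeration),
and cheap at the obstacle counts that subpathway overlap produces.

"Largest and widest" is resolved as: primary key area, secondary key
width, then topmost, then leftmost. The label font starts at the maximum
(24 pt) and shrinks in 1 pt steps until the greedily word-wrapped text fits
the winning rectangle; below the minimum (8 pt) the label is omitted
entirely rather than rendered illegibly. Font metrics are a deterministic
device-independent approximation: character advance = 0.6 × size, line
height = 1.2 × size. These are invented defaults, all configurable; the
point of the approximation is that label fitting is reproducible on any
machine, not typographic fidelity.

Highlight opacity at zoom z is 1 below `fade_start` (default 0.6), 0 above
`fade_end` (default 1.0), linear in between — the boxes guide orientation
in zoomed-out views and get out of the way at reaction-level zoom. The
production thresholds of the system this emulates are unpublished; ours are
plain defaults.

## EHLD annotation and interaction

The annotation convention is an element-id scheme: `REGION-<stableId>`,
`TEXT-<stableId>`, `OVERLAY-<stableId>` (prefixes configurable, see
`docs/format-ehld.md`). A duplicate region id is a hard error; a region
missing its label or overlay is kept as a partial region with a warning.

Hit-testing uses exact containment for rect/circle/ellipse/polygon
(polygons via shapely), and the bounding box for path elements — full
Bézier containment is out of scope, and the fixture paths are polygonal so
the approximation is exact there. Element transforms are not interpreted;
documents using `transform` on annotated elements are outside the supported
dialect. The topmost hit is the region latest in document order, matching
painter's order.

Interaction states are explicit attribute edits (stroke overlays for
highlighted/selected, a marker dot for flagged), never CSS classes, so an
exported file renders identically in any viewer. Original attribute values
are stashed in a `data-pv-orig` attribute on the element; returning to
`normal` restores them and removes the stash, so the serialized document is
byte-equal to the original.

## Over-representation analysis and overlay

The p-value is the hypergeometric upper tail `P(X ≥ k)` with population
size = |universe|, successes = pathway set size, draws = |query ∩ universe|.
It is computed by scipy's survival function, which works in log-space and
is stable for large sets; the test suite pins it to exact rational
summation within 1e-12 on universes up to 60. Query identifiers outside
the universe are dropped with a logged count; a fully disjoint query is an
error, not a silent all-ones result. Identifiers are opaque strings — any
mapping between identifier namespaces happens upstream.

BH-FDR is the standard step-up `min_{k≥i} p_(k)·m/k`, capped at 1,
implemented in a few numpy lines and cross-checked in tests against both
the literal enumeration and statsmodels.

Colour encodes the p-value: linear RGB interpolation between the profile's
gradient endpoints parameterized by `p/threshold` for `p <` threshold
(default 0.05), and the profile grey for `p ≥` threshold. The grey switch
at the threshold is the only discontinuity. The hit bar under the label is
anchored bottom-left with width exactly `found/total ×` label width. All
overlay elements live in one `analysis-overlay` SVG group, so re-applying
results is idempotent (the group is replaced) and export-without-overlay is
a pure strip. The legend colours by p-value, not FDR; the FDR is printed in
the per-pathway annotation as `k/N  FDR = x.xxE±ee`.

## Presentation export

The export maps the diagram to an `AnchoredShapeGraph`: node glyphs become
autoshapes (preset geometry per glyph class), each reaction gets an 8×8
reaction-centre shape, and every polyline with k interior bends contributes
k invisible anchor shapes (2×2 units, no line, no fill — invisible but
still selectable in editors) and k+1 straight connectors chained
node → anchor → … → reaction-centre. Straight connectors are used because
the source polylines already encode the bends, which preserves the
published layout exactly. Backbone endpoints resolve to the node or
reaction-centre shape they touch (within ε), falling back to an anchor;
participant polylines always chain from their node shape to the
reaction-centre shape. Output arrows become connector head decorations on
the node-side segment; catalysis circles and inhibition bars become small
decoration shapes grouped with their adjacent connector segment so the
ending travels with its line. Dashed "uncertain" styles map to dashed
connector lines.

The OOXML package is written directly: content types, relationships,
presentation, one slide, minimal layout/master/theme. Scale: 1 canvas
unit = 9525 EMU (96 units/inch). Connection sites on node shapes use the
nearest of the four side midpoints to the opposite endpoint (preset-rect
site order top/left/bottom/right). Connector `xfrm` frames are derived
from the referenced shapes' sites — editors recompute them on move; the
attachment itself is carried by the `stCxn`/`endCxn` id references, which
is the testable form of "connected objects must follow". Zip entries use a
fixed timestamp, so identical graphs give byte-identical files.

`verify_export` reopens the package and checks: required parts present,
every relationship target resolves, every connector carries both
connection references and they point at shapes present on the slide, and
no shape frame exceeds the slide bounds.

## Synthetic fixtures

The generator family is seeded and pure: identical specs give
byte-identical outputs, which is itself one of the tested contracts.
Diagrams place glyphs on a jittered grid (no overlap by construction),
join each reaction's input to a nearby output through a 0–2-bend backbone
ending at the reaction point, attach optional catalyst/inhibitor
participants, and partition reactions into spatially contiguous subpathway
chunks. EHLD fixtures cycle region shapes through rect/circle/polygon/path
to exercise every hit-testing branch and always include unannotated
decorations. Analysis fixtures plant one enriched pathway: with the default
conditions (universe 200, set size 20, query 20, hit fraction 0.8 — i.e. 16
planted members plus 4 background identifiers), the planted pathway should
attain the minimal p-value in at least 45 of 50 replicates; the suite
measures this directly.

What the fixtures do **not** emulate: biologically meaningful topology,
realistic glyph aspect ratios or label lengths, curved reaction routing,
transformed/nested SVG coordinate systems, or identifier-namespace
mismatch between query and pathway sets. Passing tests therefore
demonstrate geometric, statistical and structural correctness of the
machinery, not robustness to arbitrary hand-drawn artwork.

## Problem sizes

The default test surface uses diagrams of ~12 nodes/6 reactions (up to
1000 nodes in the round-trip test and 50 reactions in the export loop),
universes of 200 entities over 10 pathway sets, and 50-replicate recovery
sweeps; the whole suite and the acceptance script each run in well under a
minute on one CPU.

## Known limitations

- Path hit-testing is bounding-box only; EHLDs relying on concave path
  regions will over-report hits near the path's corners.
- SVG `transform` attributes are ignored during geometry extraction.
- The PPTX theme/master is minimal; colour-profile theming of slide
  masters is out of scope (shapes are styled inline).
- The empty-rectangle search is exact but quadratic-ish in obstacle count;
  fine for tens of obstacles, not meant for thousands.
- `hit_bar_rect` and the overlay annotations assume horizontally laid-out
  labels.
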