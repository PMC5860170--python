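# pathviz

A toolkit for interactive pathway-diagram visualization, built around three
capabilities that pathway databases need when they move beyond static
pictures:

1. **Interactive high-level diagrams (EHLDs).** Textbook-style SVG
   illustrations of higher-level biological processes become interactive
   through three kinds of technical annotation keyed by stable pathway
   identifiers: a clickable *region* per subpathway, its *label* text, and an
   *overlay target* for analysis results. Everything unannotated is a
   decoration and is never touched. The toolkit parses these documents,
   hit-tests clicks, applies hover/selection/flagging states, and exports the
   SVG with or without analysis overlays baked in.
2. **Subpathway highlighting in classic diagrams.** In a zoomed-out
   lower-level pathway diagram, each subpathway gets a coloured box bounding
   the geometry of its member reactions. The subpathway name is placed by a
   space-partitioning rule: among the maximal axis-aligned empty rectangles
   of the box (obstacles are the overlaps with every other box), the label
   goes into the largest and widest one, at the biggest font that fits, or is
   omitted if even the minimum font does not fit. Boxes fade out linearly as
   the user zooms toward reaction-level detail.
3. **Editable presentation export.** A classic diagram is exported as a
   single-slide PPTX in which every glyph is a shape and every reaction line
   is a chain of connectors whose endpoints are *references to shape ids,
   never coordinates* — so moved glyphs keep their lines attached. Polyline
   bends become invisible anchor shapes; catalysis/inhibition line endings
   are grouped with their connector segment.

Analysis overlays use classic over-representation analysis: for a query of
$N$ identifiers drawn from a universe of $M$ entities and a pathway
containing $n$ of them, the p-value of seeing $k$ or more hits is the
hypergeometric upper tail

$$P(X \ge k) = \sum_{i=k}^{\min(n,N)} \frac{\binom{n}{i}\binom{M-n}{N-i}}{\binom{M}{N}},$$

adjusted across pathways with the Benjamini–Hochberg step-up FDR. On the
diagram, the label is covered by a rectangle whose colour encodes the
p-value (gradient below the significance threshold, grey at or above it) and
underlined by a bar whose width is exactly the hit fraction
`found/total` of the label width; hit counts and FDR are printed beside the
label and a legend bar with per-pathway ticks sits at the right edge.

Everything runs offline: a seeded fixture generator emulates all five input
kinds (diagram JSON, hierarchy JSON, annotated EHLD SVG, GMT pathway sets,
query lists).

## Worked example

```sh
pathviz synth --seed 1 --out fixture
pathviz highlight --diagram fixture/diagram.json --out highlighted.svg
pathviz overlay --ehld fixture/ehld.svg --sets fixture/sets.gmt \
    --query fixture/query.txt --out overlaid.svg
pathviz export-pptx --diagram fixture/diagram.json --out diagram.pptx
pathviz verify --pptx diagram.pptx
```

The `export-pptx` step logs

```
INFO pathviz: wrote diagram.pptx: 27 shapes, 27 connectors, 4 groups
```

— 12 entity glyphs, 6 reaction-centre shapes, the invisible anchors at
polyline bends and 4 grouped line-ending decorations, joined by 27
referenced connectors (one per polyline segment). `verify` then reports

```json
{
  "missingParts": [],
  "unresolvedRelationships": [],
  "danglingRefs": 0,
  "unattachedConnectors": 0,
  "outOfBounds": 0,
  "shapes": 27,
  "connectors": 27,
  "ok": true
}
```

meaning every package part is present, every connector carries both a start
and an end reference to a shape that exists on the slide, and nothing lies
outside the slide bounds — the structural form of "moved glyphs keep their
lines attached". `overlaid.svg` contains one coloured rectangle, hit bar and
`found/total FDR = …` annotation per analysed subpathway plus the legend
bar; `highlighted.svg` shows the subpathway boxes with their placed labels.

File formats are documented in `docs/format-diagram.md` (with a JSON-Schema
in `docs/diagram.schema.json`) and `docs/format-ehld.md`; the modelling and
algorithmic choices in `docs/methods.md`.

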