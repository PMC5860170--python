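# EHLD annotation dialect

An EHLD is a plain SVG 1.1 document (a `viewBox` is required — it defines
the canvas) in which interactivity is declared purely through element ids.
Three annotation types exist, keyed by the subpathway's stable identifier:

| element id | meaning |
| --- | --- |
| `REGION-<stableId>` | clickable area representing the subpathway |
| `TEXT-<stableId>` | text element holding the subpathway name |
| `OVERLAY-<stableId>` | element to be covered by analysis results |

Every element carrying none of these ids is a **decoration**: it is never
modified, never hit-tests, and survives all operations byte-identically.

The prefixes are this dialect's convention, not a standard; they are
configurable via `AnnotationPrefixes` when parsing documents that use a
different scheme.

Constraints and behaviour:

- A stable id may appear in at most one `REGION-` element (duplicates are a
  parse error). A region without its `TEXT-`/`OVERLAY-` partner parses with
  a warning as a partial active region; such regions still hit-test and take
  interaction states, but analysis overlays fall back to the label element
  or skip the region.
- Region geometry may be `rect`, `circle`, `ellipse`, `polygon` (exact
  containment), `path` (bounding-box containment) or a `g` grouping any of
  these (union). `transform` attributes are not interpreted.
- Overlapping regions resolve to the one latest in document order (painted
  on top).
- Interaction states write explicit presentation attributes
  (`stroke`/`stroke-width` for highlighted/selected; a `FLAG-<stableId>`
  marker dot for flagged) plus bookkeeping attributes `data-pv-state` and
  `data-pv-orig`; setting the state back to `normal` removes all of them and
  restores the original attribute values exactly.
- Analysis overlays live in a single `<g id="analysis-overlay">` appended to
  the root: one `overlay-rect`, one `hit-bar` and one annotation text per
  analysed region, plus a `analysis-legend` group at the right edge.
  Exporting with `include_overlay=False` strips exactly this group.
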