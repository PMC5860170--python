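# Diagram exchange format

A diagram file is UTF-8 JSON with canonical serialization (sorted keys,
2-space indent) so that write∘read is byte-stable. `schemaVersion` is
currently `1`. Unknown top-level keys are preserved on round trip.
A machine-readable JSON-Schema lives in `diagram.schema.json`.

Top-level keys:

| key | content |
| --- | --- |
| `schemaVersion` | integer, currently 1 |
| `pathwayId` | stable identifier of the pathway this diagram depicts |
| `canvas` | `{x, y, w, h}` in canvas units (origin top-left, y down) |
| `nodes` | list of glyphs |
| `edges` | list of reaction edges |
| `compartments` | list of cellular compartments (optional) |
| `subpathways` | embedded subpathway assignment (optional) |

Node:

```json
{"id": "N-SYN-0001", "schemaClass": "protein", "displayName": "Entity 1",
 "bounds": {"x": 30.0, "y": 40.0, "w": 70.0, "h": 36.0},
 "compartmentId": "C-SYN-001"}
```

`schemaClass` is one of `protein, chemical, complex, entity_set, gene, rna,
process_node` — a minimal subset of SBGN process-description glyph classes.

Edge:

```json
{"id": "R-SYN-RXN-0001",
 "reactionPoint": [150.0, 60.0],
 "segments": [[100.0, 55.0], [125.0, 70.0], [150.0, 60.0]],
 "connectors": [
   {"role": "input",  "nodeId": "N-SYN-0001",
    "points": [[100.0, 55.0], [150.0, 60.0]], "ending": "none"},
   {"role": "output", "nodeId": "N-SYN-0002",
    "points": [[205.0, 66.0], [150.0, 60.0]], "ending": "arrow"}
 ]}
```

`segments` is the backbone polyline; connector `points` run from the node
toward the reaction centre and must terminate within the endpoint tolerance
(default 0.5 units) of the backbone or the reaction point. Endings are
constrained by role: `arrow` → output, `circle` → catalyst/activator,
`bar` → inhibitor, `none` → any.

Compartment: `{id, name, outer: rect, inner?: rect}` with `inner` strictly
inside `outer` (the membrane ring).

Subpathway assignment:

```json
{"parentPathwayId": "R-SYN-00001",
 "groups": {"R-SYN-SP-001": ["R-SYN-RXN-0001", "R-SYN-RXN-0002"]},
 "displayNames": {"R-SYN-SP-001": "Synthetic subpathway A"}}
```

Each reaction id must exist in the parent diagram and may belong to at most
one group.

# Hierarchy format

Flat entry list with child references, so structural mistakes are
detectable:

```json
{"root": "R-SYN-ROOT",
 "entries": [
   {"stableId": "R-SYN-ROOT", "name": "Synthetic root",
    "kind": "higher_level", "children": ["R-SYN-1001"]},
   {"stableId": "R-SYN-1001", "name": "Synthetic process 1",
    "kind": "lower_level", "children": []}
 ]}
```

Rules: stable ids unique, exactly one parent per entry, no cycles,
`lower_level` entries are leaves.

# Colour profile format

```json
{"name": "custom",
 "nodeFill":   {"protein": "#8DC7BB", "chemical": "#A5D791", "...": "..."},
 "nodeStroke": {"protein": "#545454", "...": "..."},
 "subpathwayPalette": ["#E415A560", "..."],
 "overlayGradient": ["#FFFF33", "#FF6600"],
 "notSignificantColor": "#C8C8C8",
 "hitBarColor": "#FFD700"}
```

Colours are `#RRGGBB` or `#RRGGBBAA`; the subpathway palette needs at least
eight distinct entries. Built-in presets: `modern`, `standard`.
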