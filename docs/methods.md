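# Methods

## Exposure model

The model is purely distance-threshold based: no concentration, decay
kinetics or sediment transport physics. A river reach is "potentially
exposed" if it lies within a commodity-dependent channel distance
downstream of a pollutant entry point, or inside a mine footprint.
Results are therefore an exposure *extent*, not an impact magnitude.

### Hydrography

The river network is a forest: each segment has at most one downstream
pointer, oriented toward terminal sinks; braided reaches are rejected
at load. Offsets along a segment are measured in km from the upstream
endpoint, and sub-reach intervals are half-open `[start, end)`, which
makes downstream accumulation and cropping order-independent. Loaders
verify and repair vertex orientation (upstream → downstream) using
downstream connectivity, since vector hydrography does not guarantee
vertex order. Two measurement modes run through the package: *planar*
(coordinates already in km; exact arithmetic, used by the synthetic
worlds and most tests) and *geodesic* (WGS84 lon/lat; lengths by
Vincenty's formulae, verified against a meridian-arc series oracle to
1 ppm).

### Linkage

The centroid-based entry uses a representative interior point (never
the geometric centroid, which can fall outside concave footprints; for
multi-part footprints, the largest part). The point is walked
cell-to-cell down the D8 grid until a stream cell is reached; the entry
offset is the projection of that cell's centre onto the segment
polyline. The 10 km buffer is applied as *straight-line* distance from
the mine point to the candidate entry, not path length (consistent with
reporting linkage distances as geodesic averages). D8 codes default to
the ESRI convention (1=E, 2=SE, …, 128=NE, 0=sink) but the code table
is configurable. A loop guard bounds every walk by the grid cell
count; the guard warns and excludes the mine rather than hanging on a
cyclic flow field.

The intersection-based route treats every maximal river interval inside
the footprint as directly exposed, and each interval's downstream end
is a propagation start. The attenuation budget restarts at zero at the
exit point: the in-mine interval does not consume budget, since
propagation is counted from where the river leaves the polygon.

A randomized-sampling validator routes uniform interior points
downslope and reports the fraction whose entry lands on the same
downstream path (same segment or ancestor/descendant) as the
interior-point entry; sample size and the agreement definition are
parameters.

### Attenuation scenarios

| scenario | distance for commodity *c* |
|---|---|
| moderate | element-specific value if configured, else 6.5 km |
| severe | element-specific value if configured, else 45.6 km |
| uniform_lower | 6.5 km for all |
| uniform_upper | 45.6 km for all |

6.5 and 45.6 km are the shortest and longest attenuation distances
modelled by Macklin et al. (2023) for metal concentrations falling
below Dutch Intervention Limits. Element-specific values are not
hardcoded — they ship as an editable CSV config
(`src/minetrace/data/attenuation_template.csv`), and tables claiming
that provenance are bound-checked to [6.5, 45.6] at load. Mines with
several commodities take the **maximum** distance: on a single
downstream path this equals the union of per-commodity traces, which is
what per-commodity reporting implies; per-commodity group summaries
still dissolve within each group separately.

### Tracing and dissolve

Tracing consumes segments whole and crops the final one so the traced
total equals the attenuation distance exactly, stopping at sinks and
*before* any segment with limnicity above 20 %. An entry located on a
lentic segment itself yields nothing (the lentic rule excludes "the
segment itself"); direct in-mine intervals are kept regardless, since
in-mine river portions are exposed by definition. Dissolve merges
overlapping *and* endpoint-adjacent intervals per segment (adjacency
tolerance 1e-9 km planar, 1e-6 km geodesic) and unions the
source/commodity/status attribution sets; it is idempotent and never
increases total length.

### Demand-share weighting

Clean-energy scaling uses the IEA 2023 demand shares (copper 24.41 %,
lithium 55.76 %, nickel 15.40 %, cobalt 29.77 %, graphite 27.89 %, rare
earth elements 17.20 %); mines extracting several ETMs take the
arithmetic mean of their ETM shares (non-ETM commodities of mixed mines
are ignored for the share but the mine still counts fully toward every
commodity group). Weighting is applied per mine *before* the
cross-mine dissolve: each mine's own reaches are first unioned within
the mine (so a mine's centroid and exit traces are not double-counted),
scaled by its share, summed over mines, and capped per segment at the
unweighted dissolved length — preserving the interpretation of a
*share* of the affected length when several ETM mines overlap.

### Conservation overlay

Point sites with a reported area become circles of matching area
(planar buffer, or vertices from the direct geodesic problem at evenly
spaced azimuths — an azimuthal-equidistant construction); marine point
sites are excluded, and points without an area are dropped with a
warning. The combined CPA is the validity-repaired union of all PA and
KBA polygons; the strict variant keeps nationally designated PAs with
an IUCN category I–VI that are not proposed (Venter-style), plus
supplementary national-source sites retained as provided, and excludes
KBAs. Headline proportions are measured against the dissolved union;
per-site tables are measured against the original site polygons, so a
reach inside an overlapping PA and KBA counts once at the union level
but once per site — double counting is confined to the site tables.
Lines exactly on a CPA boundary count as inside (closed polygons, a
deterministic tie-break).

### Aggregation

The proportion for every unit is exposed length / total river length in
that unit. Basin rows partition the global total exactly (each segment
belongs to one basin). Commodity and status rows multi-count reaches
under every matching group, so they are not additive; for status
figures an exclusive mode is also provided that routes multi-status
reaches to a separate "multiple" row instead. Reaches from mines with
no commodity information form an "unknown" commodity row.

## Synthetic worlds

The generator builds a random spanning forest over a grid (randomized
multi-source Prim, sinks on the west edge), takes the top fraction of
cells by flow accumulation as stream cells — a downward-closed subtree,
split into confluence-to-confluence segments — and derives both the
vector network (polylines through cell centres, lengths always from
geometry) and the D8 raster from the *same* forest, so grid and network
are consistent by construction. An eastern stream-free apron drains
westward and hosts mine placements beyond the 10 km buffer.

Defaults emulate the study conditions of the global mining dataset:
48.1 % of mines carry commodity labels; 12.7 % of mines straddle a
river (the complement of the 87.3 % that do not overlap rivers; near
mines are rejection-sampled clear of the stream lines to keep this
fraction in control); activity statuses mix 14.2 % active / 26.2 %
inactive / 1 % planned / rest unknown, planted at cluster level through
property-point multisets whose majority realizes the planted status
(ties included, to exercise the tie → unknown rule); mine areas are
log-normal with median ≈ 0.03 km² and a heavy tail; 8 % of segments are
lentic (limnicity 25–80 %). The synthetic attenuation table (gold 14,
copper 30, coal 9.8, silver 21, nickel 18 km) contains calibration
values chosen inside the 6.5–45.6 km bounds, not literature values, so
that the moderate and severe scenarios genuinely differ.

What the generator does **not** emulate: realistic terrain or
meandering geometry, discharge-correlated network shape, spatially
clustered mining districts, or global scale. Passing tests therefore
demonstrate correctness of the algorithms and their invariants, not
that real-data headline figures are reproduced; desk-scale worlds are
far more mining-dense than the globe, so absolute percentages from the
acceptance script are much higher than any global figure.

`brute_force_exposure` recomputes each mine's exposure with plain
scalar recursion (its own D8 walk, its own budget arithmetic), shares
no tracing/interval code with the pipeline, and is used only as an
independent oracle; generated worlds carry this ground truth for all
four scenarios.

## Numerical choices

* Budget arithmetic tolerance 1e-12 km; interval-merge tolerance 1e-9
  km planar / 1e-6 km geodesic.
* `locate_offset` projects via arc-length fraction × stored length —
  exact in planar mode; points farther than a tolerance from the
  polyline raise, catching linkage bugs.
* Ties in the planted-fixture D8 derivation break by a fixed N-first
  neighbour order, keeping hand-walked paths deterministic.
* Status majority requires a *strict* mode; ties of any multiplicity
  (and empty point sets) yield "unknown".
* Degenerate inputs: polylines need ≥ 2 vertices; zero-distance traces
  and empty exposure sets return empty results rather than erroring.

## Problem sizes

Randomized test batteries use 100 worlds of ≤ 200 segments and 12 mines
(32×48 cells at 1 km) for the tracing/oracle/scenario properties, with
10-world subsets for the geometry-heavy dissolve and overlay checks;
the acceptance script runs one 64×80-cell world with 40 mines. These
sizes were chosen so the whole suite exercises thousands of
mine-scenario traces while remaining quick to iterate on.

## Known limitations

* Attenuation is a hard threshold; no decay gradient or load model.
* The lentic rule is binary at 20 % limnicity and terminates the trace
  entirely; partial transport through lakes is not modelled.
* Entry offsets inherit raster-to-vector projection error of up to
  about one cell diagonal.
* The strict-PA filter trusts the site metadata; WDPA flattening rules
  beyond the stated filter are out of scope.
* Geodesic mode measures polyline length ellipsoidally but clips
  geometries in lon/lat space (consistent with common `sf`-style
  workflows); planar mode has no such approximation.
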