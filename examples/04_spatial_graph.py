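"""Spatial-graph analyses: network distance, correlation, clustering.

Builds the z-disc/sarcomere graph for a chain whose beat phase lags
along its length (a desynchronized program), then shows that the
correlation between normalized-length series decays with network
distance — the number of connecting sarcomeres between a pair.
"""

import numpy as np

from sarcokinetics import segment, spatial_analysis, synthgen, track, tseries

scene = synthgen.baseline_scene(seed=2)
program = synthgen.ContractionProgram.beating(80, 20, peak_shortening=0.15, phase_lag=4.0)
scene = synthgen.Scene(chains=scene.chains, program=program, render=scene.render)

stack, _ = synthgen.generate_movie(scene)
discs, sarcs = segment.segment_movie(stack)
zdisc_tracks = track.track_movie(discs)
sarc_tracks = track.track_movie(sarcs)
series = tseries.build_timeseries(sarc_tracks, sarcs, seed=2)

graph = spatial_analysis.build_spatial_graph(zdisc_tracks, sarc_tracks, discs, sarcs)
print(f"graph: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges")

records = spatial_analysis.correlation_vs_distance(series, graph)
by_dist: dict[float, list[float]] = {}
for r in records:
    if np.isfinite(r.network):
        by_dist.setdefault(r.network, []).append(r.correlation)
print("network distance -> mean correlation:")
for d in sorted(by_dist)[:8]:
    print(f"  {int(d):2d} hops: {np.mean(by_dist[d]):+.3f}")
# The monotone decay shows nearby sarcomeres beat nearly in phase while
# distant ones drift apart — the phase gradient written into the program.

Z, order = spatial_analysis.cluster_timeseries(series, metric="euclidean")
# with a 4-frame lag per sarcomere and a 40-frame beat, sarcomeres 10
# apart beat exactly in phase — the dendrogram pairs them up
print(f"dendrogram leaf order: {[int(i) for i in order]}")

params = spatial_analysis.timeseries_parameters(series[0].y)
print(f"timing of sarcomere {series[0].global_id}: {params}")
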