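from types import SimpleNamespace

import pytest

from sarcokinetics import segment, synthgen, track, tseries


@pytest.fixture(scope="session")
def baseline():
    """Fully processed baseline validation scene: one sinusoidal chain of
    20 sarcomeres beating homogeneously (15% peak shortening, 80 frames,
    low Perlin noise), run through segmentation, tracking, and GP time
    series with default parameters."""
    scene = synthgen.baseline_scene(seed=1)
    stack, gt = synthgen.generate_movie(scene)
    discs, sarcs = segment.segment_movie(stack.astype(float))
    zdisc_tracks = track.track_movie(discs)
    sarc_tracks = track.track_movie(sarcs)
    series = tseries.build_timeseries(sarc_tracks, sarcs, seed=1)
    return SimpleNamespace(
        scene=scene,
        stack=stack,
        gt=gt,
        discs=discs,
        sarcs=sarcs,
        zdisc_tracks=zdisc_tracks,
        sarc_tracks=sarc_tracks,
        series=series,
        n_frames=stack.shape[0],
    )
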