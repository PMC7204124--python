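"""Shared test utilities: dataset-to-sequence plumbing and a brute-force DTW oracle."""

from __future__ import annotations

import numpy as np

import vdsmon as vm
from vdsmon.classifier import LabeledSample

# ---------------------------------------------------------------------------
# Labeled velocity sequences from synthetic data


def sequences_from_videos(profiles, n_per_class, seed, scene=None, diff_cfg=None):
    """Full chain: render videos, run three-frame differencing, extract speeds."""
    scene = scene or vm.default_scene()
    samples = vm.generate_dataset(n_per_class, scene, profiles, seed)
    out = []
    for s in samples:
        track = vm.track_from_frames(s.frames, diff_cfg)
        out.append(LabeledSample(vm.velocity_sequence(track), s.label))
    return out


def sequences_from_tracks(profiles, n_per_class, seed, scene=None):
    """Cheap chain: speeds straight from scripted ground-truth tracks (no pixels)."""
    scene = scene or vm.default_scene()
    pos, neg = profiles
    child = np.random.SeedSequence(seed).generate_state(2 * n_per_class, dtype=np.uint32) % (2**31)
    out = []
    i = 0
    for _ in range(n_per_class):
        for prof in (pos, neg):
            sc = vm.SceneConfig(**{**scene.__dict__, "seed": int(child[i])})
            track = vm.generate_track(sc, prof)
            out.append(LabeledSample(vm.velocity_sequence(track), prof.class_label))
            i += 1
    return out


# ---------------------------------------------------------------------------
# Independent DTW oracle: exhaustive enumeration of monotone warping paths.
# Stays free of the dynamic program it checks: every admissible path is
# listed recursively and its cost summed directly.

_STEPS = {
    "standard_a": ((-1, -1), (-1, 0), (0, -1)),
    "extended_b": ((-1, -1), (-2, -1), (-1, -2)),
}


def enumerate_paths(M, N, constraint="standard_a", boundary="standard"):
    """All warping paths ending at (M-1, N-1) admissible under the rules."""
    steps = _STEPS[constraint]

    def start_ok(pi, pj):
        if boundary == "paper_literal":
            return pi < 0 or pj < 0
        return pi == -1 and pj == -1

    def rec(i, j):
        paths = []
        for di, dj in steps:
            pi, pj = i + di, j + dj
            if pi >= 0 and pj >= 0:
                for p in rec(pi, pj):
                    paths.append(p + [(i, j)])
            elif start_ok(pi, pj):
                paths.append([(i, j)])
        return paths

    return rec(M - 1, N - 1)


def brute_dtw(a, b, constraint="standard_a", boundary="standard", local_cost="absolute"):
    """Minimum summed local cost over exhaustively enumerated paths (inf if none)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    best = np.inf
    for path in enumerate_paths(len(a), len(b), constraint, boundary):
        cost = 0.0
        for i, j in path:
            d = a[i] - b[j]
            cost += d * d if local_cost == "squared" else abs(d)
        best = min(best, cost)
    return best
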