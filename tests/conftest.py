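import io

import numpy as np
import pytest

from gcross import RatingCube, VarianceComponents
from gcross.presets import COMPONENT_PRESETS


@pytest.fixture
def t3_behavioural() -> VarianceComponents:
    """LAST/MH behavioural component column (the published G-study table)."""
    return VarianceComponents.from_values(
        COMPONENT_PRESETS["last_mh_behavioural"], n_p=10, n_t=2, n_r=2
    )


@pytest.fixture
def make_cube():
    """Factory for a cube from a raw array, with auto-generated labels."""

    def _make(scores, measure="behavioural"):
        scores = np.asarray(scores, dtype=float)
        n_p, n_t, n_r = scores.shape
        return RatingCube(
            persons=tuple(f"P{i}" for i in range(n_p)),
            tasks=tuple(f"T{j}" for j in range(n_t)),
            raters=tuple(f"R{k}" for k in range(n_r)),
            measure=measure,
            scores=scores,
        )

    return _make


@pytest.fixture
def random_cube(make_cube):
    """Factory for a random cube of a given shape and seed."""

    def _make(n_p, n_t, n_r, seed=0, integer=False):
        rng = np.random.default_rng(seed)
        if integer:
            scores = rng.integers(1, 10, size=(n_p, n_t, n_r)).astype(float)
        else:
            scores = rng.uniform(1.0, 9.0, size=(n_p, n_t, n_r))
        return make_cube(scores)

    return _make


@pytest.fixture
def ratings_csv_text():
    """A complete balanced 2x2x2 behavioural design as CSV text."""

    def _text(scores=None):
        lines = ["person_id,task_id,rater_id,measure,score"]
        default = iter(range(8))
        for p in ("A", "B"):
            for t in ("LAST", "MH"):
                for r in ("R1", "R2"):
                    s = next(default) % 9 + 1 if scores is None else scores[(p, t, r)]
                    lines.append(f"{p},{t},{r},behavioural,{s}")
        return "\n".join(lines) + "\n"

    return _text


@pytest.fixture
def csv_stream():
    def _stream(text: str):
        return io.StringIO(text)

    return _stream
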