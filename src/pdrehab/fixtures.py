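"""Small deterministic populations used by the test suite and documentation.

Each fixture is generated programmatically (nothing is shipped as data):

- ``two_neuron_worked_example``: the two-neuron population with encoding PDs
  at 30 and 60 degrees whose noiseless PV points at 45 degrees — an
  equalized stand-in for a single neuron tuned to 45.
- ``uniform_intact``: an equally spaced intact population.
- ``post_lesion``: the uniform population after the default directional
  lesion.
"""

from __future__ import annotations

from pathlib import Path

from .conditions import ConfigurationError
from .population import Population
from .rehab import LesionSpec, apply_lesion

FIXTURE_KINDS = ("two_neuron_worked_example", "uniform_intact", "post_lesion")


def make_fixture(
    kind: str, n: int = 8, lesion: LesionSpec | None = None
) -> Population:
    if kind == "two_neuron_worked_example":
        return Population(base_pd=[30.0, 60.0])
    if kind == "uniform_intact":
        return Population.uniform(n)
    if kind == "post_lesion":
        return apply_lesion(Population.uniform(n), lesion or LesionSpec())
    raise ConfigurationError(
        f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}"
    )


def write_fixture(kind: str, out_path: str | Path, n: int = 8) -> Path:
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    make_fixture(kind, n=n).to_csv(out)
    return out
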