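"""Host ionic-model definitions.

Each model module exposes the same flat interface: ``STATE_NAMES``,
``CURRENT_NAMES``, ``PARAM_NAMES``, ``DEFAULT_PARAMS``,
``initial_state(n)`` and a numba-compiled ``step(S, P, dt, istim,
clamped, IOUT)`` kernel operating on column-per-node arrays.
:class:`ModelDef` wraps a module for the simulation engine.
"""

from dataclasses import dataclass
from types import ModuleType

from ..errors import UnsupportedModelError
from . import guineapig, human, toy


@dataclass(frozen=True)
class ModelDef:
    """Handle to one ionic model's kernel and metadata."""

    name: str
    module: ModuleType

    @property
    def state_names(self):
        return self.module.STATE_NAMES

    @property
    def current_names(self):
        return self.module.CURRENT_NAMES

    @property
    def param_names(self):
        return self.module.PARAM_NAMES

    @property
    def default_params(self):
        return self.module.DEFAULT_PARAMS.copy()

    @property
    def default_rate_hz(self):
        return self.module.DEFAULT_RATE_HZ

    @property
    def default_stim(self):
        return self.module.DEFAULT_STIM

    @property
    def step(self):
        return self.module.step

    def initial_state(self, n=1):
        return self.module.initial_state(n)

    @property
    def n_state(self):
        return len(self.module.STATE_NAMES)

    @property
    def n_current(self):
        return len(self.module.CURRENT_NAMES)


MODEL_REGISTRY = {
    "human": ModelDef("human", human),
    "guineapig": ModelDef("guineapig", guineapig),
    "toy": ModelDef("toy", toy),
}


def get_model(species: str) -> ModelDef:
    try:
        return MODEL_REGISTRY[species]
    except KeyError:
        raise UnsupportedModelError(
            f"unknown species {species!r}; available: "
            f"{sorted(MODEL_REGISTRY)}"
        ) from None
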