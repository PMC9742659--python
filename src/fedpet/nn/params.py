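"""Named parameter stores and their flat-vector form.

Federated training exchanges a single flat parameter vector theta between the
server and the centers; the model addresses parameters by stable names.  A
:class:`ParameterVector` bridges the two views losslessly.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

__all__ = ["ParameterVector"]


class ParameterVector:
    """An ordered mapping name -> ndarray with a lossless flat view.

    Two vectors built from the same model configuration are conformable:
    same names, same order, same shapes.
    """

    def __init__(self, arrays: "OrderedDict[str, np.ndarray]"):
        self._arrays = OrderedDict((k, np.asarray(v)) for k, v in arrays.items())

    def __getitem__(self, name: str) -> np.ndarray:
        return self._arrays[name]

    def __iter__(self):
        return iter(self._arrays)

    def items(self):
        return self._arrays.items()

    def __len__(self):
        return len(self._arrays)

    @property
    def n_params(self) -> int:
        return sum(a.size for a in self._arrays.values())

    @property
    def dtype(self):
        return next(iter(self._arrays.values())).dtype

    def shapes(self) -> "OrderedDict[str, tuple]":
        return OrderedDict((k, a.shape) for k, a in self._arrays.items())

    def to_flat(self) -> np.ndarray:
        return np.concatenate([a.ravel() for a in self._arrays.values()])

    def from_flat(self, flat: np.ndarray) -> "ParameterVector":
        """New ParameterVector with this one's structure and ``flat``'s values."""
        flat = np.asarray(flat)
        if flat.ndim != 1 or flat.size != self.n_params:
            raise ValueError(
                f"flat vector of size {flat.size} does not match {self.n_params} parameters"
            )
        out = OrderedDict()
        pos = 0
        for k, a in self._arrays.items():
            out[k] = flat[pos : pos + a.size].reshape(a.shape).astype(a.dtype, copy=True)
            pos += a.size
        return ParameterVector(out)

    def conformable_with(self, other: "ParameterVector") -> bool:
        return self.shapes() == other.shapes()

    def copy(self) -> "ParameterVector":
        return ParameterVector(OrderedDict((k, a.copy()) for k, a in self._arrays.items()))
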