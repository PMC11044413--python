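"""Diffusion-weighting (b-value) schemes and the per-model b-value subsets.

The acquisition protocol this package targets samples nine b-values,
0-2000 s/mm2.  The three signal models deliberately use different subsets:

* mono-exponential ADC uses the two-point pair (0, 750),
* the IVIM bi-exponential uses b <= 1000 (perfusion decays too fast to
  inform higher weightings),
* the three-compartment restriction-spectrum model uses all nine values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

#: Default multi-b-value protocol, s/mm2.
DEFAULT_BVALUES = (0.0, 50.0, 100.0, 250.0, 500.0, 750.0, 1000.0, 1500.0, 2000.0)

#: Highest b-value entering the IVIM fit, s/mm2.
IVIM_MAX_B = 1000.0

#: b-value paired with b=0 for the two-point ADC estimate, s/mm2.
MONO_HIGH_B = 750.0


@dataclass(frozen=True)
class BValueScheme:
    """Ordered diffusion weightings with the per-model subsets.

    Parameters
    ----------
    values
        Strictly increasing b-values in s/mm2; the first must be 0.
    """

    values: tuple[float, ...] = DEFAULT_BVALUES
    mono_high_b: float = MONO_HIGH_B
    ivim_max_b: float = IVIM_MAX_B
    _array: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise InvalidInputError("a b-value scheme needs at least two values")
        if arr[0] != 0.0:
            raise InvalidInputError("the first b-value must be 0")
        if not np.all(np.diff(arr) > 0):
            raise InvalidInputError("b-values must be strictly increasing")
        if self.mono_high_b not in arr:
            raise InvalidInputError(
                f"mono-exponential b-value {self.mono_high_b} missing from scheme"
            )
        object.__setattr__(self, "values", tuple(arr.tolist()))
        object.__setattr__(self, "_array", arr)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def array(self) -> np.ndarray:
        """All b-values as a float array (read-only view)."""
        a = self._array.view()
        a.flags.writeable = False
        return a

    @property
    def mono_subset(self) -> np.ndarray:
        """The (0, high-b) pair used by the two-point ADC estimate."""
        return np.array([0.0, self.mono_high_b])

    @property
    def mono_indices(self) -> np.ndarray:
        return np.array([0, int(np.flatnonzero(self._array == self.mono_high_b)[0])])

    @property
    def ivim_subset(self) -> np.ndarray:
        """b-values entering the bi-exponential IVIM fit (b <= ivim_max_b)."""
        return self._array[self._array <= self.ivim_max_b].copy()

    @property
    def ivim_indices(self) -> np.ndarray:
        return np.flatnonzero(self._array <= self.ivim_max_b)

    @property
    def rsi_subset(self) -> np.ndarray:
        """All b-values (the restriction-spectrum fit uses the full scheme)."""
        return self._array.copy()


DEFAULT_SCHEME = BValueScheme()
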