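"""Network structure and parameter containers for the bilinear neuronal model.

A network is a small directed graph of brain regions. Its dynamics follow the
bilinear state equation

    dx/dt = (A + sum_j u_j(t) B^(j)) x + C u(t)

where ``A`` holds endogenous coupling rates (Hz), each ``B^(j)`` the additive
change of those rates under modulatory input j, and ``C`` the strengths of
direct driving inputs. The observation side (balloon haemodynamics) lives in
:mod:`genembed.forward`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkSpec",
    "NeuronalParams",
    "HemodynamicParams",
    "BoldRecord",
    "wm_network",
    "default_hemodynamics",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Structural skeleton: which A/B/C entries are allowed to be non-zero.

    Masks use the convention ``mask[target, source]``; the diagonal of
    ``a_mask`` (self-connections) is always allowed.
    """

    region_names: tuple[str, ...]
    a_mask: np.ndarray
    b_masks: tuple[np.ndarray, ...]
    c_mask: np.ndarray
    input_names: tuple[str, ...] = ()

    def __post_init__(self):
        r = len(self.region_names)
        a = np.asarray(self.a_mask, bool)
        if a.shape != (r, r):
            raise ValueError(f"a_mask must be {r}x{r}, got {a.shape}")
        if not np.all(np.diag(a)):
            raise ValueError("diagonal of a_mask (self-connections) must be allowed")
        for j, b in enumerate(self.b_masks):
            if np.asarray(b).shape != (r, r):
                raise ValueError(f"b_masks[{j}] must be {r}x{r}")
        c = np.asarray(self.c_mask, bool)
        if c.ndim != 2 or c.shape[0] != r:
            raise ValueError("c_mask must be regions x inputs")
        if c.shape[1] != len(self.b_masks):
            raise ValueError("c_mask must have one column per input")
        if not c.any():
            raise ValueError("at least one driving input is required")
        object.__setattr__(self, "a_mask", a)
        object.__setattr__(self, "b_masks", tuple(np.asarray(b, bool) for b in self.b_masks))
        object.__setattr__(self, "c_mask", c)
        if not self.input_names:
            object.__setattr__(
                self, "input_names", tuple(f"u{j}" for j in range(c.shape[1]))
            )

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def n_inputs(self) -> int:
        return self.c_mask.shape[1]

    def free_parameter_names(self) -> list[str]:
        """Names of the free neuronal parameters, in documented order.

        Order: A entries column-by-column (source-major, i.e. all targets of
        region 1 first), then each B matrix likewise, then C. This matches the
        row order in which coupling tables for this network are usually
        printed.
        """
        names = []
        r = self.n_regions
        rn = self.region_names
        for s in range(r):
            for t in range(r):
                if self.a_mask[t, s]:
                    label = f"A: {rn[s]} self" if s == t else f"A: {rn[s]}->{rn[t]}"
                    names.append(label)
        for j, b in enumerate(self.b_masks):
            for s in range(r):
                for t in range(r):
                    if b[t, s]:
                        names.append(f"B({self.input_names[j]}): {rn[s]}->{rn[t]}")
        for j in range(self.n_inputs):
            for t in range(r):
                if self.c_mask[t, j]:
                    names.append(f"C: {self.input_names[j]}->{rn[t]}")
        return names

    @property
    def n_free_parameters(self) -> int:
        return (
            int(self.a_mask.sum())
            + int(sum(b.sum() for b in self.b_masks))
            + int(self.c_mask.sum())
        )


def wm_network() -> NetworkSpec:
    """Three-region visual-parietal-prefrontal working-memory network.

    Visual input drives VC; the working-memory (2-back) condition modulates
    VC->DLPFC and DLPFC->PC. The endogenous A matrix is fully connected.
    With three regions this yields 12 free neuronal parameters
    (9 A + 2 B + 1 C).
    """
    a = np.ones((3, 3), bool)
    b_vis = np.zeros((3, 3), bool)  # the driving input modulates nothing
    b_wm = np.zeros((3, 3), bool)
    b_wm[2, 0] = True  # VC -> DLPFC
    b_wm[1, 2] = True  # DLPFC -> PC
    c = np.zeros((3, 2), bool)
    c[0, 0] = True  # visual input drives VC
    return NetworkSpec(
        region_names=("VC", "PC", "DLPFC"),
        a_mask=a,
        b_masks=(b_vis, b_wm),
        c_mask=c,
        input_names=("visual", "wm"),
    )


@dataclass
class NeuronalParams:
    """Coupling rates of the bilinear neuronal model, all in Hz."""

    A: np.ndarray
    B: list[np.ndarray]
    C: np.ndarray
    spec: NetworkSpec | None = None

    def __post_init__(self):
        self.A = np.asarray(self.A, float)
        self.B = [np.asarray(b, float) for b in self.B]
        self.C = np.atleast_2d(np.asarray(self.C, float))
        r = self.A.shape[0]
        if self.A.shape != (r, r):
            raise ValueError("A must be square")
        if np.any(np.diag(self.A) >= 0):
            raise ValueError("diagonal of A (self-inhibition) must be strictly negative")
        for b in self.B:
            if b.shape != (r, r):
                raise ValueError("each B matrix must match A's shape")
        if self.C.shape[0] != r or self.C.shape[1] != len(self.B):
            raise ValueError("C must be regions x inputs with one column per input")
        if self.spec is not None:
            if not _respects_mask(self.A, self.spec.a_mask, allow_diag=True):
                raise ValueError("A has entries outside the allowed mask")
            for b, m in zip(self.B, self.spec.b_masks):
                if not _respects_mask(b, m):
                    raise ValueError("B has entries outside the allowed mask")
            if not _respects_mask(self.C, self.spec.c_mask):
                raise ValueError("C has entries outside the allowed mask")

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]

    def to_vector(self, spec: NetworkSpec) -> np.ndarray:
        """Flatten to the free-parameter vector in `spec` order."""
        out = [self.A.T[spec.a_mask.T]]
        for b, m in zip(self.B, spec.b_masks):
            out.append(b.T[m.T])
        out.append(self.C.T[spec.c_mask.T])
        return np.concatenate(out)

    @classmethod
    def from_vector(cls, theta: np.ndarray, spec: NetworkSpec) -> "NeuronalParams":
        theta = np.asarray(theta, float)
        if theta.size != spec.n_free_parameters:
            raise ValueError(
                f"expected {spec.n_free_parameters} parameters, got {theta.size}"
            )
        r = spec.n_regions
        pos = 0
        A = np.zeros((r, r))
        k = int(spec.a_mask.sum())
        A.T[spec.a_mask.T] = theta[pos : pos + k]
        pos += k
        B = []
        for m in spec.b_masks:
            b = np.zeros((r, r))
            k = int(m.sum())
            b.T[m.T] = theta[pos : pos + k]
            pos += k
            B.append(b)
        C = np.zeros((r, spec.n_inputs))
        k = int(spec.c_mask.sum())
        C.T[spec.c_mask.T] = theta[pos : pos + k]
        return cls(A=A, B=B, C=C, spec=spec)


def _respects_mask(m: np.ndarray, mask: np.ndarray, allow_diag: bool = False) -> bool:
    forbidden = ~mask
    if allow_diag:
        forbidden = forbidden & ~np.eye(mask.shape[0], dtype=bool)
    return not np.any(m[forbidden] != 0)


# Classical balloon-model defaults (1.5 T coefficient set).
_HEMO_DEFAULTS = {
    "signal_decay": 0.64,  # kappa, 1/s
    "autoregulation": 0.32,  # gamma, 1/s
    "transit_time": 2.0,  # tau, s
    "stiffness": 0.32,  # alpha, unitless
    "oxygen_extraction": 0.32,  # rho, unitless
}


@dataclass
class HemodynamicParams:
    """Per-region balloon-model parameters plus the resting venous volume fraction."""

    signal_decay: np.ndarray  # kappa (1/s)
    autoregulation: np.ndarray  # gamma (1/s)
    transit_time: np.ndarray  # tau (s)
    stiffness: np.ndarray  # alpha (unitless, in (0,1))
    oxygen_extraction: np.ndarray  # rho (unitless, in (0,1))
    resting_volume_fraction: float = 0.02  # V0

    def __post_init__(self):
        for name in (
            "signal_decay",
            "autoregulation",
            "transit_time",
            "stiffness",
            "oxygen_extraction",
        ):
            v = np.atleast_1d(np.asarray(getattr(self, name), float))
            if np.any(v <= 0):
                raise ValueError(f"{name} must be strictly positive")
            setattr(self, name, v)
        for name in ("stiffness", "oxygen_extraction"):
            if np.any(getattr(self, name) >= 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.resting_volume_fraction <= 0:
            raise ValueError("resting_volume_fraction must be positive")

    @property
    def n_regions(self) -> int:
        return self.signal_decay.size


def default_hemodynamics(n_regions: int) -> HemodynamicParams:
    """Published balloon-model values, replicated across regions."""
    return HemodynamicParams(
        signal_decay=np.full(n_regions, _HEMO_DEFAULTS["signal_decay"]),
        autoregulation=np.full(n_regions, _HEMO_DEFAULTS["autoregulation"]),
        transit_time=np.full(n_regions, _HEMO_DEFAULTS["transit_time"]),
        stiffness=np.full(n_regions, _HEMO_DEFAULTS["stiffness"]),
        oxygen_extraction=np.full(n_regions, _HEMO_DEFAULTS["oxygen_extraction"]),
    )


@dataclass
class BoldRecord:
    """Scans x regions BOLD matrix in percent signal change."""

    y: np.ndarray
    TR: float
    region_names: tuple[str, ...]

    def __post_init__(self):
        self.y = np.atleast_2d(np.asarray(self.y, float))
        if not np.all(np.isfinite(self.y)):
            raise ValueError("BOLD matrix contains non-finite entries")
        if self.y.shape[1] != len(self.region_names):
            raise ValueError("column count must match region_names")
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        self.region_names = tuple(self.region_names)

    @property
    def n_scans(self) -> int:
        return self.y.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_scans) * self.TR
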