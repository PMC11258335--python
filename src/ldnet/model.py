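"""LDNet assembly: paired dynamics/reconstruction networks with embedded
normalization layers and optional structural constraints.

The latent dynamics network maps (latent state, normalized input) to a
latent time derivative scaled by 1/dt_ref.  The reconstruction network maps
(latent state, [normalized input,] normalized query coordinate) to the
output field in raw units.  Two constraints can be imposed by construction:

* equilibrium: subtracting the network evaluated at (0, u_eq) makes the
  origin an exact fixed point of the latent dynamics for any weights;
* prescribed values on a region (e.g. Dirichlet data): the reconstruction
  becomes y_lift(x) + (trainable part)(x) * psi(x), with psi vanishing
  exactly on the prescribed region.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .data import ChannelStats, NormalizationStats
from .nets import FCNN, glorot_init, tail_compress

__all__ = ["LDNet", "DirichletConstraint", "box_boundary_mask", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_SCHEMA = "ldnet-checkpoint-v1"


@dataclass
class DirichletConstraint:
    """Lift/mask pair enforcing prescribed output values where psi(x) = 0."""

    lift: callable  # x (n, d) -> (n, d_y)
    mask: callable  # x (n, d) -> (n,)


def box_boundary_mask(bounds):
    """Product-of-distances mask for a box domain.

    Vanishes exactly on the whole box boundary and is positive inside;
    scaled so its maximum (at the box center) is 1.
    """
    bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
    half = 0.5 * (bounds[:, 1] - bounds[:, 0])
    scale = np.prod(half**2)

    def psi(x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.prod((x - bounds[:, 0]) * (bounds[:, 1] - x), axis=1) / scale

    return psi


@dataclass
class LDNet:
    """Paired dynamics/reconstruction networks with shared normalization state."""

    dyn: FCNN
    rec: FCNN
    d_s: int
    stats: NormalizationStats
    dt: float
    rec_uses_u: bool = False
    u_eq: np.ndarray | None = None
    dirichlet: DirichletConstraint | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("integration step dt must be positive")
        if self.u_eq is not None:
            self.u_eq = np.atleast_1d(np.asarray(self.u_eq, dtype=float))
        d_u, d = self.d_u, self.dim
        if self.dyn.widths[0] != self.d_s + d_u or self.dyn.widths[-1] != self.d_s:
            raise ValueError(
                f"dynamics network widths {self.dyn.widths} inconsistent with "
                f"d_s={self.d_s}, d_u={d_u}"
            )
        rec_in = self.d_s + (d_u if self.rec_uses_u else 0) + d
        if self.rec.widths[0] != rec_in:
            raise ValueError(
                f"reconstruction network input width {self.rec.widths[0]} != {rec_in}"
            )
        if self.rec.widths[-1] != self.d_y:
            raise ValueError("reconstruction network output width != d_y")

    # -- dimensions --------------------------------------------------------
    @property
    def d_u(self) -> int:
        return self.stats.u.center.size

    @property
    def d_y(self) -> int:
        return self.stats.y.center.size

    @property
    def dim(self) -> int:
        return self.stats.x.center.size

    @property
    def n_params(self) -> int:
        return self.dyn.n_params + self.rec.n_params

    def init_weights(self, seed: int) -> "LDNet":
        """Glorot-uniform weights / zero biases for both networks."""
        glorot_init(self.dyn, seed)
        glorot_init(self.rec, seed + 1)
        return self

    # -- latent dynamics ---------------------------------------------------
    def equilibrium_term(self) -> np.ndarray | None:
        """Dynamics-network output at (s=0, u=u_eq), or None if unset."""
        if self.u_eq is None:
            return None
        feat = np.concatenate([np.zeros(self.d_s), self.stats.u.normalize(self.u_eq)])
        return self.dyn.forward(feat)

    def dyn_rhs(self, s, u):
        """Latent time derivative ds/dt for raw-unit inputs u.

        Accepts single vectors or batches (rows).  With the equilibrium
        constraint set, (s=0, u=u_eq) maps to exactly zero for any weights.
        """
        s = np.asarray(s, dtype=float)
        u = np.asarray(u, dtype=float)
        if not (np.all(np.isfinite(s)) and np.all(np.isfinite(u))):
            raise ValueError("non-finite latent state or input")
        single = s.ndim == 1
        S = s[None, :] if single else s
        U = u[None, :] if u.ndim == 1 else u
        feat = np.concatenate([S, self.stats.u.normalize(U)], axis=1)
        out = self.dyn.forward(feat)
        eq = self.equilibrium_term()
        if eq is not None:
            out = out - eq
        out = out / self.stats.dt_ref
        return out[0] if single else out

    # -- field reconstruction ---------------------------------------------
    def rec_features(self, s, u, x) -> np.ndarray:
        S = np.atleast_2d(np.asarray(s, dtype=float))
        X = np.atleast_2d(np.asarray(x, dtype=float))
        parts = [S]
        if self.rec_uses_u:
            U = np.atleast_2d(np.asarray(u, dtype=float))
            parts.append(self.stats.u.normalize(U))
        parts.append(self.stats.x.normalize(X))
        return np.concatenate(parts, axis=1)

    def rec_output_to_field(self, raw: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Map raw reconstruction-network output to the field in raw units."""
        r = raw
        if self.stats.beta is not None:
            r = tail_compress(r, self.stats.beta)
        y = self.stats.y.denormalize(r)
        if self.dirichlet is not None:
            X = np.atleast_2d(np.asarray(x, dtype=float))
            y = self.dirichlet.lift(X) + y * self.dirichlet.mask(X)[:, None]
        return y

    def reconstruct(self, s, u, x):
        """Output field at query points x given latent state s and input u."""
        x_arr = np.atleast_2d(np.asarray(x, dtype=float))
        xn = self.stats.x.normalize(x_arr)
        if np.any(np.abs(xn) > 1.0 + 1e-9):
            raise ValueError("query point outside the domain bounding box")
        single = np.asarray(s).ndim == 1 and np.asarray(x).ndim == 1
        feat = self.rec_features(s, u, x_arr)
        y = self.rec_output_to_field(np.atleast_2d(self.rec.forward(feat)), x_arr)
        return y[0] if single else y


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: LDNet, path) -> None:
    if model.dirichlet is not None:
        warnings.warn(
            "Dirichlet lift/mask callbacks are not serializable and are not "
            "stored in the checkpoint; re-attach them after loading",
            stacklevel=2,
        )
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = CHECKPOINT_SCHEMA
        f.attrs["d_s"] = model.d_s
        f.attrs["dt"] = model.dt
        f.attrs["rec_uses_u"] = model.rec_uses_u
        f.attrs["dt_ref"] = model.stats.dt_ref
        for name, net in (("dyn", model.dyn), ("rec", model.rec)):
            g = f.create_group(name)
            g.attrs["widths"] = net.widths
            for l, (W, b) in enumerate(zip(net.weights, net.biases)):
                g.create_dataset(f"W{l}", data=W)
                g.create_dataset(f"b{l}", data=b)
        g = f.create_group("stats")
        for name, ch in (("u", model.stats.u), ("y", model.stats.y), ("x", model.stats.x)):
            g.create_dataset(f"{name}_center", data=ch.center)
            g.create_dataset(f"{name}_width", data=ch.width)
            g.attrs[f"{name}_strategy"] = json.dumps(ch.strategy)
        if model.stats.beta is not None:
            g.create_dataset("beta", data=model.stats.beta)
        if model.u_eq is not None:
            f.create_dataset("u_eq", data=model.u_eq)


def load_checkpoint(path) -> LDNet:
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError("not an LDNet checkpoint (schema tag mismatch)")
        nets = {}
        for name in ("dyn", "rec"):
            g = f[name]
            net = FCNN(list(g.attrs["widths"]))
            for l in range(len(net.weights)):
                net.weights[l] = g[f"W{l}"][...]
                net.biases[l] = g[f"b{l}"][...]
            nets[name] = net
        g = f["stats"]
        channels = {
            name: ChannelStats(
                g[f"{name}_center"][...],
                g[f"{name}_width"][...],
                json.loads(g.attrs[f"{name}_strategy"]),
            )
            for name in ("u", "y", "x")
        }
        stats = NormalizationStats(
            u=channels["u"],
            y=channels["y"],
            x=channels["x"],
            dt_ref=float(f.attrs["dt_ref"]),
            beta=g["beta"][...] if "beta" in g else None,
        )
        return LDNet(
            dyn=nets["dyn"],
            rec=nets["rec"],
            d_s=int(f.attrs["d_s"]),
            stats=stats,
            dt=float(f.attrs["dt"]),
            rec_uses_u=bool(f.attrs["rec_uses_u"]),
            u_eq=f["u_eq"][...] if "u_eq" in f else None,
        )
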