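"""Coordination-shell models of the absorber environment.

A :class:`ShellModel` is the structural hypothesis an EXAFS refinement
tests: an ordered list of Gaussian coordination shells, each carrying a
multiplicity N, a mean absorber-neighbor distance r (A) and a mean square
relative displacement sigma2 (A^2), plus the global amplitude reduction
factor S0^2 and edge-energy shift dE (eV).

Presets encode the heme-Fe(III) site of human serum heme-albumin: the four
porphyrin nitrogens, the axial Tyr phenoxy oxygen, and the first two carbon
rings of the macrocycle, in both the crystallographic and the
EXAFS-refined geometry, plus a drug-bound variant with a sixth (histidine
Nε-like) nitrogen neighbor at 2.15 A.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

_PARAMS = ("N", "r", "sigma2")


@dataclass(frozen=True)
class Shell:
    """One Gaussian coordination shell.

    ``free_flags`` marks which of (N, r, sigma2) a refinement may vary;
    ``bounds`` optionally maps a parameter name to a (low, high) pair.
    ``sigma2_tied_to`` names another shell whose sigma2 this shell shares
    during refinement (used for weak shells whose disorder is not
    independently determined).
    """

    label: str
    element: str
    N: float
    r: float
    sigma2: float
    free_flags: tuple = (False, True, True)
    bounds: dict = field(default_factory=dict)
    sigma2_tied_to: str | None = None

    def __post_init__(self):
        if not self.N > 0:
            raise ValueError(f"shell {self.label}: N must be > 0, got {self.N}")
        if not self.r > 0:
            raise ValueError(f"shell {self.label}: r must be > 0, got {self.r}")
        if self.sigma2 < 0:
            raise ValueError(
                f"shell {self.label}: sigma2 must be >= 0, got {self.sigma2}"
            )
        for name, (lo, hi) in self.bounds.items():
            if name not in _PARAMS:
                raise ValueError(f"unknown bounded parameter {name!r}")
            value = getattr(self, name)
            if not lo <= value <= hi:
                raise ValueError(
                    f"shell {self.label}: bound ({lo}, {hi}) does not bracket "
                    f"{name}={value}"
                )

    def free(self, name):
        return self.free_flags[_PARAMS.index(name)]


@dataclass(frozen=True)
class ShellModel:
    """Ordered shells plus the global S0^2 and dE parameters."""

    shells: tuple
    s02: float = 0.85
    delta_e: float = 0.0
    s02_free: bool = False
    delta_e_free: bool = False

    def __post_init__(self):
        object.__setattr__(self, "shells", tuple(self.shells))
        if not 0.0 < self.s02 <= 1.2:
            raise ValueError(f"S0^2 must be in (0, 1.2], got {self.s02}")
        if abs(self.delta_e) >= 20.0:
            raise ValueError(f"|dE| must be < 20 eV, got {self.delta_e}")
        labels = [s.label for s in self.shells]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate shell labels in {labels}")

    def __getitem__(self, label):
        for s in self.shells:
            if s.label == label:
                return s
        raise KeyError(label)

    @property
    def labels(self):
        return tuple(s.label for s in self.shells)

    def add_shell(self, shell):
        """Return a new model extended by ``shell`` (immutably)."""
        if shell.label in self.labels:
            raise ValueError(f"duplicate shell label {shell.label!r}")
        return replace(self, shells=self.shells + (shell,))

    def drop_shell(self, label):
        """Return a new model without the named shell."""
        self[label]
        return replace(
            self, shells=tuple(s for s in self.shells if s.label != label)
        )

    def replace_shell(self, label, **changes):
        """Return a new model with one shell's fields changed."""
        shells = tuple(
            replace(s, **changes) if s.label == label else s for s in self.shells
        )
        return replace(self, shells=shells)

    # -- flat config-block serialization (key = value text) ----------------

    def to_config(self):
        """Serialize as a flat ``key = value`` block (text)."""
        buf = io.StringIO()
        buf.write(f"s02 = {self.s02!r}\n")
        buf.write(f"s02_free = {int(self.s02_free)}\n")
        buf.write(f"delta_e = {self.delta_e!r}\n")
        buf.write(f"delta_e_free = {int(self.delta_e_free)}\n")
        for i, s in enumerate(self.shells):
            p = f"shell{i}."
            buf.write(f"{p}label = {s.label}\n")
            buf.write(f"{p}element = {s.element}\n")
            for name in _PARAMS:
                buf.write(f"{p}{name} = {getattr(s, name)!r}\n")
            buf.write(
                f"{p}free = {','.join(str(int(f)) for f in s.free_flags)}\n"
            )
            for name, (lo, hi) in s.bounds.items():
                buf.write(f"{p}bound.{name} = {lo!r},{hi!r}\n")
            if s.sigma2_tied_to:
                buf.write(f"{p}sigma2_tied_to = {s.sigma2_tied_to}\n")
        return buf.getvalue()

    @classmethod
    def from_config(cls, text):
        """Parse the block written by :meth:`to_config`."""
        entries = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            entries[key.strip()] = value.strip()
        shells = []
        i = 0
        while f"shell{i}.label" in entries:
            p = f"shell{i}."
            bounds = {}
            for name in _PARAMS:
                if f"{p}bound.{name}" in entries:
                    lo, hi = entries[f"{p}bound.{name}"].split(",")
                    bounds[name] = (float(lo), float(hi))
            shells.append(
                Shell(
                    label=entries[p + "label"],
                    element=entries[p + "element"],
                    N=float(entries[p + "N"]),
                    r=float(entries[p + "r"]),
                    sigma2=float(entries[p + "sigma2"]),
                    free_flags=tuple(
                        bool(int(f)) for f in entries[p + "free"].split(",")
                    ),
                    bounds=bounds,
                    sigma2_tied_to=entries.get(p + "sigma2_tied_to"),
                )
            )
            i += 1
        return cls(
            shells=tuple(shells),
            s02=float(entries["s02"]),
            delta_e=float(entries["delta_e"]),
            s02_free=bool(int(entries.get("s02_free", "0"))),
            delta_e_free=bool(int(entries.get("delta_e_free", "0"))),
        )


def _exafs_shells(sigma_scale_34=1.0):
    return (
        Shell("I Fe-N", "N", 4, 2.07, 4.1e-3),
        Shell("II Fe-O", "O", 1, 2.48, 1.1e-3),
        Shell("III Fe-C1", "C", 8, 3.09, 13e-3 * sigma_scale_34),
        Shell("IV Fe-C2", "C", 4, 3.50, 5e-3 * sigma_scale_34),
    )


_PRESETS = {}

_PRESETS["pdb_4plus1"] = ShellModel(
    shells=(
        Shell("I Fe-N", "N", 4, 2.06, 3e-3),
        Shell("II Fe-O", "O", 1, 2.78, 3e-3),
        Shell("III Fe-C1", "C", 8, 3.07, 6e-3),
        Shell("IV Fe-C2", "C", 4, 3.43, 6e-3),
    ),
    s02=0.85,
    delta_e=0.0,
)

_PRESETS["exafs_4plus1"] = ShellModel(
    shells=_exafs_shells(),
    s02=0.85,
    delta_e=1.35,
)

_PRESETS["xanes_model"] = ShellModel(
    shells=(
        Shell("I Fe-N", "N", 4, 2.07, 4.1e-3),
        Shell("II Fe-O", "O", 1, 2.54, 1.1e-3),
        Shell("III Fe-C1", "C", 8, 3.08, 13e-3),
        Shell("IV Fe-C2", "C", 4, 3.55, 5e-3),
        Shell("Fe-C4", "C", 8, 4.23, 6e-3),
    ),
    s02=0.85,
    delta_e=1.35,
)

# Drug-bound (hexa-coordinated) construction: the ligand-free best fit plus
# a sixth nitrogen neighbor at 2.15 A (His Nε-like), with the outer carbon
# shells' disorder halved to reflect the drug-induced steric tightening of
# the heme pocket.  The sixth shell's sigma2 is tied to shell I.
_PRESETS["drug_5plus1"] = ShellModel(
    shells=_exafs_shells(sigma_scale_34=0.5)
    + (Shell("Nb Fe-N", "N", 1, 2.15, 4.1e-3, sigma2_tied_to="I Fe-N"),),
    s02=0.85,
    delta_e=1.35,
)


def preset_shell_model(name):
    """Return a packaged heme-site shell model by name.

    Valid names: ``pdb_4plus1`` (crystallographic geometry),
    ``exafs_4plus1`` (EXAFS-refined geometry, the ligand-free best fit),
    ``xanes_model`` (near-edge modelling geometry, includes the outer C4
    ring), ``drug_5plus1`` (drug-bound six-coordinate construction).
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {sorted(_PRESETS)}"
        ) from None
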