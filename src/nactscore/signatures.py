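"""Declarative signature definitions and the shipped default configurations.

A signature is a linear score over gene-level expression: genes are either
members of a named gene group (the group score is a weighted mean of its
members, and groups enter the score through ``group_weights``) or singletons
entering the score directly through ``singleton_weights``.  An optional
threshold policy floors one group at a percentile of its distribution in a
reference population before the score is combined.

Two defaults ship with the package as editable YAML files:

* ``rs21`` — the 21-gene Recurrence Score approximation: proliferation, ER,
  HER2 and invasion gene groups plus three singleton genes, with an
  80th-percentile floor on the proliferation group referenced to ER-positive
  patients.
* ``ms12`` — the 12-gene Molecular Score approximation: eight target genes as
  singletons, proliferation-axis genes positively and ER-axis genes
  negatively weighted.

Because downstream analysis z-scores the raw scores per cohort, results are
invariant to positive affine rescaling of either weight set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ValidationError

MS12_TARGET_GENES = ("AZGP1", "BIRC5", "DHCR7", "IL6ST", "MGP", "RBBP8", "STC2", "UBE2C")
RS21_TARGET_GENES = (
    "AURKA", "BAG1", "BCL2", "BIRC5", "CCNB1", "CD68", "CTSL2", "ERBB2",
    "ESR1", "GRB7", "GSTM1", "MKI67", "MMP11", "MYBL2", "PGR", "SCUBE2",
)


@dataclass(frozen=True)
class ThresholdPolicy:
    """Percentile floor applied to one gene group before score combination.

    ``reference`` names the population whose distribution defines the
    percentile; the only rule currently implemented is ``er_positive``
    (ER-positive samples within each cohort).
    """

    group: str
    percentile: float
    reference: str = "er_positive"

    def __post_init__(self) -> None:
        if not 0.0 <= self.percentile <= 100.0:
            raise ValidationError(f"threshold percentile {self.percentile} not in [0, 100]")
        if self.reference != "er_positive":
            raise ValidationError(f"unknown threshold reference rule '{self.reference}'")


@dataclass
class SignatureDefinition:
    """Genes, groups, weights and threshold policy of one linear signature."""

    name: str
    groups: dict[str, dict[str, float]] = field(default_factory=dict)
    group_weights: dict[str, float] = field(default_factory=dict)
    singleton_weights: dict[str, float] = field(default_factory=dict)
    threshold: ThresholdPolicy | None = None

    def __post_init__(self) -> None:
        if set(self.groups) != set(self.group_weights):
            raise ValidationError(
                f"signature '{self.name}': groups and group_weights must name "
                f"the same groups"
            )
        seen: set[str] = set()
        for gname, members in self.groups.items():
            if not members:
                raise ValidationError(f"signature '{self.name}': empty group '{gname}'")
            overlap = seen & set(members)
            if overlap:
                raise ValidationError(
                    f"signature '{self.name}': gene(s) {sorted(overlap)} appear "
                    "in more than one place"
                )
            seen |= set(members)
        overlap = seen & set(self.singleton_weights)
        if overlap:
            raise ValidationError(
                f"signature '{self.name}': gene(s) {sorted(overlap)} are both "
                "group members and singletons"
            )
        if self.threshold is not None and self.threshold.group not in self.groups:
            raise ValidationError(
                f"signature '{self.name}': threshold group "
                f"'{self.threshold.group}' is not a defined group"
            )

    @property
    def genes(self) -> list[str]:
        """All genes the signature needs, groups first, in definition order."""
        out: list[str] = []
        for members in self.groups.values():
            out.extend(members)
        out.extend(self.singleton_weights)
        return out

    def with_percentile(self, percentile: float) -> "SignatureDefinition":
        """Copy of this signature with the floor percentile replaced."""
        if self.threshold is None:
            raise ValidationError(f"signature '{self.name}' has no threshold policy")
        thr = ThresholdPolicy(self.threshold.group, percentile, self.threshold.reference)
        return SignatureDefinition(
            self.name, dict(self.groups), dict(self.group_weights),
            dict(self.singleton_weights), thr,
        )


def _from_dict(d: dict) -> SignatureDefinition:
    thr = d.get("threshold")
    policy = None
    if thr:
        policy = ThresholdPolicy(
            group=str(thr["group"]),
            percentile=float(thr["percentile"]),
            reference=str(thr.get("reference", "er_positive")),
        )
    return SignatureDefinition(
        name=str(d["name"]),
        groups={g: {k: float(v) for k, v in m.items()} for g, m in (d.get("groups") or {}).items()},
        group_weights={g: float(w) for g, w in (d.get("group_weights") or {}).items()},
        singleton_weights={g: float(w) for g, w in (d.get("singleton_weights") or {}).items()},
        threshold=policy,
    )


def load_signature(path: str | Path) -> SignatureDefinition:
    """Load a signature definition from a YAML config file."""
    with open(path) as fh:
        return _from_dict(yaml.safe_load(fh))


def _load_packaged(name: str) -> SignatureDefinition:
    text = resources.files("nactscore.data").joinpath(name).read_text()
    return _from_dict(yaml.safe_load(text))


def default_ms12() -> SignatureDefinition:
    """The shipped 12-gene Molecular Score configuration."""
    sig = _load_packaged("ms12.yaml")
    _check_ms12_structure(sig)
    return sig


def default_rs21() -> SignatureDefinition:
    """The shipped 21-gene Recurrence Score configuration."""
    sig = _load_packaged("rs21.yaml")
    _check_rs21_structure(sig)
    return sig


def _check_ms12_structure(sig: SignatureDefinition) -> None:
    """Validate sign pattern and gene set of an MS-type config (magnitudes
    are free: z-scoring makes the analysis invariant to positive rescaling)."""
    if set(sig.singleton_weights) != set(MS12_TARGET_GENES):
        raise ValidationError("ms12 config must cover exactly the 8 target genes")
    positive = {"BIRC5", "UBE2C", "DHCR7"}
    for gene, w in sig.singleton_weights.items():
        want_pos = gene in positive
        if (w > 0) != want_pos or w == 0:
            raise ValidationError(
                f"ms12 config: weight for {gene} must be "
                f"{'positive' if want_pos else 'negative'} (got {w})"
            )


def _check_rs21_structure(sig: SignatureDefinition) -> None:
    if set(sig.genes) != set(RS21_TARGET_GENES):
        raise ValidationError("rs21 config must cover exactly the 16 target genes")
    expected_groups = {"proliferation", "er", "her2", "invasion"}
    if set(sig.groups) != expected_groups:
        raise ValidationError(f"rs21 config must define groups {sorted(expected_groups)}")
    signs = {"proliferation": 1, "er": -1, "her2": 1, "invasion": 1}
    for g, s in signs.items():
        if sig.group_weights[g] * s <= 0:
            raise ValidationError(f"rs21 config: group '{g}' weight has the wrong sign")
    if sig.threshold is None or sig.threshold.group != "proliferation":
        raise ValidationError("rs21 config must floor the proliferation group")
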