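"""Synthetic protein families for offline benchmarking.

Real marker-protein families (terminase subunits, portal) are defined by
conserved sequence motifs embedded in otherwise variable sequence.  The
generator emulates exactly that structure: a family is a set of consensus
motifs planted at anchored positions inside random background sequence,
with a per-residue substitution rate mu controlling divergence within the
family.  "Others" are pure background (no motifs), so class separability
is governed solely by the motifs.  Open-set negatives come from *novel*
families never seen in training — optionally derived from a target family
by perturbing its consensus motifs, which emulates remote homologs, the
main source of false positives on real metagenomes.

Everything is deterministic given a seed: the same seed yields
byte-identical FASTA output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from phagemark.encoding import DEFAULT_ALPHABET
from phagemark.sequence_io import OTHERS, LabeledDataset, ProteinRecord

MIN_LENGTH = 30  # residues; sequences are clamped to at least this


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *stream]))


@dataclass(frozen=True)
class FamilyProfile:
    """A protein family: anchored consensus motifs over background."""

    name: str
    motifs: tuple[tuple[str, float], ...]  # (consensus, anchor fraction in [0,1])
    length_mean: float = 300.0
    length_sd: float = 40.0
    background_frequencies: tuple[float, ...] = tuple([0.05] * 20)

    def __post_init__(self) -> None:
        for consensus, anchor in self.motifs:
            if len(consensus) < 3:
                raise ValueError(f"motif {consensus!r} shorter than 3 residues")
            if not (0.0 <= anchor <= 1.0):
                raise ValueError(f"anchor fraction {anchor} outside [0, 1]")
        total = float(np.sum(self.background_frequencies))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {total}, not 1")

    @property
    def motif_budget(self) -> int:
        return sum(len(c) for c, _ in self.motifs)


@dataclass(frozen=True)
class BenchmarkSpec:
    """Counts and rates for a full train/test/open-set benchmark.

    Defaults give the standard desk-scale benchmark: 3 families with 500
    training / 200 test members each, 800 training background "others"
    (test others scaled by n_test/n_train), 5,000 open-set sequences from
    families absent from training, and within-family substitution rate 0.1.
    """

    n_train: int = 500
    n_test: int = 200
    n_others: int = 800
    n_others_test: int | None = None
    n_openset: int = 5000
    substitution_rate: float = 0.1
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_test, self.n_others, self.n_openset) < 0:
            raise ValueError("counts must be >= 0")
        if not (0.0 <= self.substitution_rate < 1.0):
            raise ValueError(f"substitution_rate {self.substitution_rate} outside [0, 1)")
        if not (0.0 <= self.indel_rate < 1.0):
            raise ValueError(f"indel_rate {self.indel_rate} outside [0, 1)")

    @property
    def others_test(self) -> int:
        if self.n_others_test is not None:
            return self.n_others_test
        if self.n_train == 0:
            return 0
        return round(self.n_others * self.n_test / self.n_train)


def make_family_profile(
    name: str,
    n_motifs: int = 2,
    motif_len: int = 15,
    length_mean: float = 300.0,
    length_sd: float = 40.0,
    seed: int = 0,
) -> FamilyProfile:
    """Draw a family with random consensus motifs at spaced anchors."""
    if n_motifs < 1:
        raise ValueError("need at least one motif")
    if motif_len * n_motifs > length_mean:
        raise ValueError(
            f"{n_motifs} motifs of {motif_len} residues cannot fit a mean "
            f"length of {length_mean:g}"
        )
    rng = _rng(seed, 0x9F)
    alpha = list(DEFAULT_ALPHABET)
    # evenly spaced anchor slots with jitter keep motifs non-overlapping
    slots = np.linspace(0.1, 0.85, n_motifs)
    jitter = rng.uniform(-0.03, 0.03, size=n_motifs) if n_motifs > 1 else np.zeros(1)
    motifs = tuple(
        ("".join(rng.choice(alpha, size=motif_len)), float(np.clip(s + j, 0.0, 1.0)))
        for s, j in zip(slots, jitter)
    )
    return FamilyProfile(name=name, motifs=motifs,
                         length_mean=length_mean, length_sd=length_sd)


def perturb_profile(
    profile: FamilyProfile, divergence: float, name: str, seed: int = 0
) -> FamilyProfile:
    """Derive a novel family by mutating a fraction of each consensus.

    The result shares the parent's anchors and composition but has every
    motif changed in at least one position — a remote homolog of the
    parent family, useful as a hard open-set negative.
    """
    if not (0.0 < divergence <= 1.0):
        raise ValueError("divergence must be in (0, 1]")
    rng = _rng(seed, 0xD1)
    alpha = DEFAULT_ALPHABET
    new_motifs = []
    for consensus, anchor in profile.motifs:
        chars = list(consensus)
        n_mut = max(1, int(round(divergence * len(chars))))
        for pos in rng.choice(len(chars), size=n_mut, replace=False):
            choices = [a for a in alpha if a != chars[pos]]
            chars[pos] = choices[rng.integers(len(choices))]
        new_motifs.append(("".join(chars), anchor))
    return replace(profile, name=name, motifs=tuple(new_motifs))


def _mutate(consensus: str, mu: float, rng: np.random.Generator) -> str:
    if mu == 0.0:
        return consensus
    chars = list(consensus)
    hits = np.nonzero(rng.random(len(chars)) < mu)[0]
    for pos in hits:
        choices = [a for a in DEFAULT_ALPHABET if a != chars[pos]]
        chars[pos] = choices[rng.integers(len(choices))]
    return "".join(chars)


def sample_family(
    profile: FamilyProfile,
    n: int,
    mu: float = 0.0,
    indel_rate: float = 0.0,
    seed: int = 0,
    id_prefix: str | None = None,
) -> list[ProteinRecord]:
    """Sample ``n`` member sequences of a family.

    Lengths are Normal(length_mean, length_sd) truncated below at the
    motif budget (and 30 residues); background residues are i.i.d. from
    the profile's composition; each motif copy is substituted per residue
    with probability ``mu`` (uniformly among the other 19 residues) and,
    with probability ``indel_rate``, gains or loses one residue at its
    edge.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed, 0x5A)
    alpha = np.array(list(DEFAULT_ALPHABET))
    freqs = np.asarray(profile.background_frequencies)
    prefix = id_prefix or profile.name
    floor = max(profile.motif_budget, MIN_LENGTH)
    records = []
    for i in range(n):
        L = int(max(round(rng.normal(profile.length_mean, profile.length_sd)), floor))
        chars = list(rng.choice(alpha, size=L, p=freqs))
        prev_end = 0
        for consensus, anchor in sorted(profile.motifs, key=lambda m: m[1]):
            motif = _mutate(consensus, mu, rng)
            start = int(round(anchor * (L - len(motif))))
            start = min(max(start, prev_end), L - len(motif))
            chars[start : start + len(motif)] = list(motif)
            end = start + len(motif)
            if indel_rate > 0.0 and rng.random() < indel_rate:
                if rng.random() < 0.5:  # single-residue insertion after the motif
                    chars.insert(end, str(rng.choice(alpha)))
                    L += 1
                    end += 1
                elif end < L:  # or deletion of the residue following it
                    del chars[end]
                    L -= 1
            prev_end = end
        records.append(
            ProteinRecord(id=f"{prefix}_{i:05d}", sequence="".join(chars),
                          description=f"synthetic {profile.name} family member")
        )
    return records


def sample_background(
    n: int,
    length_mean: float = 300.0,
    length_sd: float = 40.0,
    seed: int = 0,
    id_prefix: str = "bg",
) -> list[ProteinRecord]:
    """Motif-free background sequences (the "others" class)."""
    rng = _rng(seed, 0xB6)
    alpha = np.array(list(DEFAULT_ALPHABET))
    records = []
    for i in range(n):
        L = int(max(round(rng.normal(length_mean, length_sd)), MIN_LENGTH))
        records.append(
            ProteinRecord(id=f"{id_prefix}_{i:05d}",
                          sequence="".join(rng.choice(alpha, size=L)),
                          description="synthetic background protein")
        )
    return records


def make_benchmark(
    target_profiles: Sequence[FamilyProfile],
    extra_profiles: Sequence[FamilyProfile],
    spec: BenchmarkSpec | None = None,
) -> dict:
    """Build train/test/open-set datasets from family profiles.

    Returns ``{"train": LabeledDataset, "test": LabeledDataset,
    "openset": [ProteinRecord]}``.  Open-set records are drawn, round
    robin, from the extra families (never seen in training) and count as
    "others" at evaluation time.
    """
    spec = spec or BenchmarkSpec()
    if spec.n_openset > 0 and not extra_profiles:
        raise ValueError("n_openset > 0 requires at least one extra family")

    mu, seed = spec.substitution_rate, spec.seed
    train_recs: list[ProteinRecord] = []
    train_labs: list[str] = []
    test_recs: list[ProteinRecord] = []
    test_labs: list[str] = []
    for fi, prof in enumerate(target_profiles):
        members = sample_family(
            prof, spec.n_train + spec.n_test, mu=mu, indel_rate=spec.indel_rate,
            seed=int(_rng(seed, 1, fi).integers(2**31)),
        )
        train_recs += members[: spec.n_train]
        train_labs += [prof.name] * spec.n_train
        test_recs += members[spec.n_train :]
        test_labs += [prof.name] * spec.n_test

    mean_len = float(np.mean([p.length_mean for p in target_profiles]))
    sd_len = float(np.mean([p.length_sd for p in target_profiles]))
    bg_train = sample_background(spec.n_others, mean_len, sd_len,
                                 seed=int(_rng(seed, 2).integers(2**31)),
                                 id_prefix="others_train")
    bg_test = sample_background(max(spec.others_test, 1), mean_len, sd_len,
                                seed=int(_rng(seed, 3).integers(2**31)),
                                id_prefix="others_test")[: spec.others_test]
    train_recs += bg_train
    train_labs += [OTHERS] * len(bg_train)
    test_recs += bg_test
    test_labs += [OTHERS] * len(bg_test)

    openset: list[ProteinRecord] = []
    if spec.n_openset > 0:
        per = np.full(len(extra_profiles), spec.n_openset // len(extra_profiles))
        per[: spec.n_openset % len(extra_profiles)] += 1
        for fi, (prof, k) in enumerate(zip(extra_profiles, per)):
            if k == 0:
                continue
            openset += sample_family(
                prof, int(k), mu=mu, indel_rate=spec.indel_rate,
                seed=int(_rng(seed, 4, fi).integers(2**31)),
            )

    order = [p.name for p in target_profiles] + [OTHERS]
    return {
        "train": LabeledDataset(records=train_recs, labels=train_labs,
                                category_order=list(order)),
        "test": LabeledDataset(records=test_recs, labels=test_labs,
                               category_order=list(order)),
        "openset": openset,
    }


def standard_profiles(seed: int = 0) -> tuple[list[FamilyProfile], list[FamilyProfile]]:
    """The default three target families plus two open-set relatives.

    Targets carry 2 motifs of 15 residues each in 300+-40-residue
    sequences.  The open-set families are remote homologs of the first two
    targets (consensus motifs perturbed at 35% of positions) — close
    enough in composition to exert false-positive pressure on the
    classifier, which is what the loss-cutoff rejection exists to absorb.
    """
    targets = [
        make_family_profile(f"F{i + 1}", n_motifs=2, motif_len=15,
                            length_mean=300.0, length_sd=40.0,
                            seed=int(_rng(seed, 7, i).integers(2**31)))
        for i in range(3)
    ]
    extras = [
        perturb_profile(targets[i], divergence=0.35, name=f"novel{i + 1}",
                        seed=int(_rng(seed, 8, i).integers(2**31)))
        for i in range(2)
    ]
    return targets, extras
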