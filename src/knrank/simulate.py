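"""Synthetic knowledge networks and patient corpora.

The real corpus this package is aimed at — gastroenterology discharge records
with multiple ICD-coded diagnoses per patient — is private, so the simulator
reproduces its published summary statistics instead: a knowledge network of
182 diseases, 1,146 clinical manifestations and 513 auxiliary examination
results; about 5,040 records drawn over 76 distinct diseases; and a mean of
3.62 diagnoses per record.  Everything else (truncated-Poisson label counts,
Bernoulli finding emission, uniform distractor findings) is an explicit
modeling choice, configurable through :class:`SimulationConfig`.

Generated surfaces are unique ASCII tokens by default (extraction is
script-agnostic); a CJK-surface mode exercises character-level tokenization.
All generators are fully deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.optimize import brentq

from .kn import (
    DEFAULT_SCHEME,
    FindingCategory,
    KnowledgeNetwork,
    Lexicon,
    WeightScheme,
    lexicon_from_kn,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "generate_kn",
    "generate_patients",
    "render_text",
    "write_records",
    "read_records",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic corpus; defaults mirror the reference dataset.

    ``n_diseases``/``n_manifestations``/``n_auxiliary`` size the knowledge
    network; patients draw their diagnoses from the first
    ``n_corpus_diseases`` diseases (a KN covers more diseases than any one
    department's case mix).  Emission probabilities are per finding category;
    ``p_noise_finding`` adds distractor findings unrelated to the gold
    diagnoses, and ``p_negated_mention`` flips mentions to negated polarity.
    """

    seed: int
    n_diseases: int = 182
    n_manifestations: int = 1146
    n_auxiliary: int = 513
    n_corpus_diseases: int = 76
    common_per_disease: tuple[int, int] = (2, 5)
    occasional_per_disease: tuple[int, int] = (2, 6)
    auxiliary_per_disease: tuple[int, int] = (1, 3)
    exclusive_auxiliary: bool = True
    manifestation_sharing: int = 0
    diseases_per_patient: float = 3.62
    p_common: float = 0.85
    p_occasional: float = 0.30
    p_auxiliary: float = 0.70
    p_noise_finding: float = 0.05
    p_negated_mention: float = 0.08
    n_patients: int = 5040
    cjk_surfaces: bool = False

    def __post_init__(self) -> None:
        for attr in (
            "p_common", "p_occasional", "p_auxiliary",
            "p_noise_finding", "p_negated_mention",
        ):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must be in [0, 1], got {v}")
        for attr in ("n_diseases", "n_manifestations", "n_auxiliary",
                     "n_corpus_diseases", "n_patients"):
            if getattr(self, attr) < 1:
                raise ValueError(f"{attr} must be positive")
        for attr in ("common_per_disease", "occasional_per_disease",
                     "auxiliary_per_disease"):
            lo, hi = getattr(self, attr)
            if not (0 <= lo <= hi):
                raise ValueError(f"{attr} range {lo, hi} invalid")
        if self.diseases_per_patient < 1.0:
            raise ValueError("diseases_per_patient must be >= 1")
        if self.n_corpus_diseases > self.n_diseases:
            raise ValueError("n_corpus_diseases cannot exceed n_diseases")
        if self.manifestation_sharing < 0:
            raise ValueError("manifestation_sharing must be >= 0")
        if self.manifestation_sharing > 0:
            total = self.n_manifestations * self.manifestation_sharing
            if total % self.n_diseases != 0:
                raise ValueError(
                    "structured sharing requires n_manifestations * "
                    "manifestation_sharing divisible by n_diseases"
                )
            if self.manifestation_sharing > self.n_diseases:
                raise ValueError("manifestation_sharing cannot exceed n_diseases")

    # -- designed regimes -------------------------------------------------
    @classmethod
    def separable(cls, seed: int, n_patients: int = 50) -> "SimulationConfig":
        """Noise-free regime where every diagnosis is exactly recoverable.

        Each disease keeps one dedicated auxiliary finding that is always
        emitted (support ratio 1, so every gold disease clears the
        threshold), and manifestations are laid out in a regular pattern —
        each shared by exactly 4 diseases while each disease carries only 3
        of them — so a disease outside the gold set can accumulate at most
        3/4 of the threshold support.  With no distractor noise and no
        negation the pipeline therefore returns precisely the gold set, for
        every seed.
        """
        return cls(
            seed=seed,
            n_diseases=40,
            n_manifestations=30,
            n_auxiliary=40,
            n_corpus_diseases=40,
            auxiliary_per_disease=(1, 1),
            exclusive_auxiliary=True,
            manifestation_sharing=4,
            p_common=0.8,
            p_occasional=0.3,
            p_auxiliary=1.0,
            p_noise_finding=0.0,
            p_negated_mention=0.0,
            n_patients=n_patients,
        )

    @classmethod
    def weight_contrast(cls, seed: int, n_patients: int = 60) -> "SimulationConfig":
        """Regime designed to separate graded weight schemes from uniform ones.

        Manifestations are drawn from a small shared pool, so the same
        finding is typically a common manifestation of a couple of diseases
        and an occasional one of several others, while auxiliary findings
        stay disease-specific but are emitted only half the time.  Graded
        weights then concentrate a shared finding's rank on the diseases it
        is common for; uniform weights spread it evenly.
        """
        return cls(
            seed=seed,
            n_diseases=30,
            n_manifestations=45,
            n_auxiliary=30,
            n_corpus_diseases=30,
            common_per_disease=(3, 3),
            occasional_per_disease=(5, 5),
            auxiliary_per_disease=(1, 1),
            exclusive_auxiliary=True,
            p_common=0.9,
            p_occasional=0.25,
            p_auxiliary=0.5,
            p_noise_finding=0.0,
            p_negated_mention=0.0,
            n_patients=n_patients,
        )


# ---------------------------------------------------------------------------
# Identifier and surface vocabularies
# ---------------------------------------------------------------------------

_CJK_DIGITS = "零一二三四五六七八九"


def _surface(prefix: str, index: int, cjk: bool) -> str:
    if not cjk:
        return f"{prefix}{index:04d}"
    head = "症" if prefix == "sx" else "检"
    return head + "".join(_CJK_DIGITS[int(c)] for c in f"{index:04d}")


def _manifestation_ids(cfg: SimulationConfig) -> list[str]:
    return [f"M{i:04d}" for i in range(cfg.n_manifestations)]


def _auxiliary_ids(cfg: SimulationConfig) -> list[str]:
    return [f"A{i:04d}" for i in range(cfg.n_auxiliary)]


def _disease_ids(cfg: SimulationConfig) -> list[str]:
    return [f"D{i:03d}" for i in range(cfg.n_diseases)]


def generate_kn(
    cfg: SimulationConfig, scheme: WeightScheme = DEFAULT_SCHEME
) -> KnowledgeNetwork:
    """Sample a bipartite disease--finding network with the configured shape.

    Per disease: common and occasional manifestations drawn without
    replacement from the shared manifestation pool (sharing across diseases
    arises naturally, and a manifestation may be common for one disease and
    occasional for another), plus auxiliary findings — one dedicated per
    disease when ``exclusive_auxiliary`` is set, extras from the shared
    auxiliary pool.  Edge weights come from the scheme via edge category.
    """
    rng = np.random.default_rng([int(cfg.seed), 101])
    kn = KnowledgeNetwork()
    d_ids = _disease_ids(cfg)
    m_ids = _manifestation_ids(cfg)
    a_ids = _auxiliary_ids(cfg)

    max_manif = cfg.common_per_disease[1] + cfg.occasional_per_disease[1]
    if max_manif > cfg.n_manifestations:
        raise ValueError(
            f"per-disease manifestation demand {max_manif} exceeds pool "
            f"of {cfg.n_manifestations}"
        )
    if cfg.exclusive_auxiliary and cfg.n_auxiliary < cfg.n_diseases:
        raise ValueError(
            "exclusive_auxiliary requires n_auxiliary >= n_diseases"
        )
    shared_aux = a_ids[cfg.n_diseases :] if cfg.exclusive_auxiliary else a_ids
    aux_min_demand = cfg.auxiliary_per_disease[0] - (1 if cfg.exclusive_auxiliary else 0)
    if aux_min_demand > len(shared_aux):
        raise ValueError(
            f"auxiliary demand {cfg.auxiliary_per_disease[0]} per disease exceeds "
            f"the shared auxiliary pool of {len(shared_aux)}"
        )

    for did in d_ids:
        kn.add_disease(did, f"disease {did[1:]}")

    def ensure_finding(fid: str) -> None:
        if fid not in kn.findings:
            idx = int(fid[1:])
            prefix = "sx" if fid.startswith("M") else "ax"
            kn.add_finding(fid, _surface(prefix, idx, cfg.cjk_surfaces))

    if cfg.manifestation_sharing > 0:
        # regular bipartite layout: manifestation j is common to exactly
        # `sharing` consecutive diseases; disease degree = total/n_diseases
        s = cfg.manifestation_sharing
        for e in range(cfg.n_manifestations * s):
            fid = m_ids[e // s]
            did = d_ids[e % cfg.n_diseases]
            ensure_finding(fid)
            kn.add_edge(fid, did, FindingCategory.COMMON, scheme.common)
    else:
        for did in d_ids:
            n_c = int(
                rng.integers(cfg.common_per_disease[0], cfg.common_per_disease[1] + 1)
            )
            n_o = int(
                rng.integers(
                    cfg.occasional_per_disease[0], cfg.occasional_per_disease[1] + 1
                )
            )
            picks = rng.choice(cfg.n_manifestations, size=n_c + n_o, replace=False)
            for j, p in enumerate(picks):
                fid = m_ids[int(p)]
                ensure_finding(fid)
                cat = FindingCategory.COMMON if j < n_c else FindingCategory.OCCASIONAL
                kn.add_edge(fid, did, cat, scheme.weight(cat))

    for k, did in enumerate(d_ids):
        n_a = int(
            rng.integers(cfg.auxiliary_per_disease[0], cfg.auxiliary_per_disease[1] + 1)
        )
        aux: list[str] = []
        if cfg.exclusive_auxiliary:
            aux.append(a_ids[k])
            n_a -= 1
        if n_a > 0 and shared_aux:
            extra = rng.choice(len(shared_aux), size=min(n_a, len(shared_aux)), replace=False)
            aux.extend(shared_aux[int(e)] for e in extra)
        for fid in aux:
            ensure_finding(fid)
            kn.add_edge(fid, did, FindingCategory.AUXILIARY, scheme.auxiliary)
    kn.validate()
    return kn


# ---------------------------------------------------------------------------
# Patient corpus
# ---------------------------------------------------------------------------


def _truncated_poisson_rate(mean: float) -> float:
    """Rate lambda such that a zero-truncated Poisson has the given mean."""
    if mean <= 1.0:
        return 1e-9
    f = lambda lam: lam / (1.0 - np.exp(-lam)) - mean
    return float(brentq(f, 1e-9, 10.0 * mean))


def _sample_gold_size(rng: np.random.Generator, lam: float, cap: int) -> int:
    while True:
        k = int(rng.poisson(lam))
        if k >= 1:
            return min(k, cap)


_EMIT_P = {
    FindingCategory.COMMON: "p_common",
    FindingCategory.OCCASIONAL: "p_occasional",
    FindingCategory.AUXILIARY: "p_auxiliary",
}


def generate_patients(kn: KnowledgeNetwork, cfg: SimulationConfig) -> list[dict]:
    """Sample a JSONL-serializable corpus of patient records against *kn*.

    Each record carries a gold diagnosis set (zero-truncated Poisson size,
    mean ``diseases_per_patient``, diseases drawn uniformly from the corpus
    subset), finding mentions emitted per category probability, distractor
    findings unrelated to the gold set, and a configurable fraction of
    negated mentions.
    """
    rng = np.random.default_rng([int(cfg.seed), 202])
    lam = _truncated_poisson_rate(cfg.diseases_per_patient)
    corpus = _disease_ids(cfg)[: cfg.n_corpus_diseases]
    findings_by_disease: dict[str, list[tuple[str, FindingCategory]]] = {}
    for (f, d), e in kn.edges.items():
        findings_by_disease.setdefault(d, []).append((f, e.category))
    for d in findings_by_disease:
        findings_by_disease[d].sort()
    all_findings = sorted(kn.findings)

    records: list[dict] = []
    for i in range(cfg.n_patients):
        size = _sample_gold_size(rng, lam, len(corpus))
        gold = sorted(
            corpus[int(j)] for j in rng.choice(len(corpus), size=size, replace=False)
        )
        emitted: set[str] = set()
        for d in gold:
            for fid, cat in findings_by_disease.get(d, []):
                if rng.random() < getattr(cfg, _EMIT_P[cat]):
                    emitted.add(fid)
        adjacent = {
            fid for d in gold for fid, _ in findings_by_disease.get(d, [])
        }
        unrelated = [f for f in all_findings if f not in adjacent]
        if cfg.p_noise_finding > 0 and unrelated:
            n_noise = int(rng.binomial(max(len(emitted), 1), cfg.p_noise_finding))
            if n_noise:
                picks = rng.choice(
                    len(unrelated), size=min(n_noise, len(unrelated)), replace=False
                )
                emitted.update(unrelated[int(p)] for p in picks)
        mentions = []
        for fid in sorted(emitted):
            negated = bool(rng.random() < cfg.p_negated_mention)
            mentions.append(
                {"surface": kn.findings[fid], "negated": negated}
            )
        records.append(
            {"id": f"pt{i:05d}", "mentions": mentions, "gold_labels": gold}
        )
    return records


# ---------------------------------------------------------------------------
# Text rendering
# ---------------------------------------------------------------------------

_FILLER_ASCII = (
    "patient reports review today stable exam ward note course follow "
    "visit general history intake chart plan status clinic entry"
).split()
_FILLER_CJK = list("天地玄黄宇宙洪荒日月盈昃辰宿列张")
_CUE_ASCII = "no"
_CUE_CJK = "无"


def render_text(
    record: dict,
    kn: KnowledgeNetwork,
    rng: np.random.Generator | None = None,
    negation_window: int = 2,
    cjk: bool | None = None,
) -> str:
    """Embed the record's finding surfaces (and cues for negated ones) in filler.

    Negated mentions get a negation cue immediately before the surface;
    mentions are separated by more filler tokens than the negation window, so
    a cue can never leak onto the following mention.  Running the extraction
    pipeline over the result recovers the record's affirmed finding set
    exactly whenever surfaces are lexicon-unique.
    """
    if rng is None:
        rng = np.random.default_rng(zlib.crc32(record["id"].encode("utf-8")))
    surfaces = set(kn.findings.values())
    if cjk is None:
        cjk = any(s and ord(s[0]) > 0x2E00 for s in surfaces)
    filler_pool = [w for w in (_FILLER_CJK if cjk else _FILLER_ASCII) if w not in surfaces]
    if len(filler_pool) < len(_FILLER_CJK if cjk else _FILLER_ASCII):
        logger.warning("filler words colliding with finding surfaces were dropped")
    cue = _CUE_CJK if cjk else _CUE_ASCII
    sep = "" if cjk else " "
    gap = negation_window + 1

    def filler(k: int) -> list[str]:
        return [filler_pool[int(j)] for j in rng.integers(0, len(filler_pool), size=k)]

    tokens: list[str] = filler(int(rng.integers(1, 4)))
    for m in record.get("mentions", []):
        if m.get("negated", False):
            tokens.append(cue)
        tokens.append(m["surface"])
        tokens.extend(filler(gap + int(rng.integers(0, 3))))
    return sep.join(tokens)


# ---------------------------------------------------------------------------
# Record JSONL I/O
# ---------------------------------------------------------------------------


def write_records(
    records: Iterable[dict], path: str | Path, metadata: dict | None = None
) -> None:
    """One JSON object per line; an optional leading ``{"_meta": ...}`` line."""
    with Path(path).open("w", encoding="utf-8") as fh:
        if metadata:
            fh.write(json.dumps({"_meta": metadata}, ensure_ascii=False) + "\n")
        for rec in records:
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_records(path: str | Path) -> list[dict]:
    """Read record JSONL, skipping metadata lines."""
    out: list[dict] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: invalid JSON ({exc})") from None
            if isinstance(obj, dict) and "_meta" in obj:
                continue
            if not isinstance(obj, dict) or "id" not in obj:
                raise ValueError(f"{path}:{lineno}: record must be an object with 'id'")
            out.append(obj)
    return out
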