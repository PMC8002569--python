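"""Sleep-stage vocabulary shared across the package.

Stages follow the Rechtschaffen & Kales six-class scheme scored on 30-s
epochs: wake (W), the four NREM sub-stages S1-S4, and REM.  The tuple
order below is the canonical class order used everywhere a class axis
appears (confusion matrices, score columns, tie-breaking).
"""

from __future__ import annotations

STAGES: tuple[str, ...] = ("W", "S1", "S2", "S3", "S4", "REM")

STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: Groups present in the study cohort: healthy plus seven sleep disorders.
GROUPS: tuple[str, ...] = (
    "healthy",
    "insomnia",
    "bruxism",
    "narcolepsy",
    "NFLE",
    "PLM",
    "RBD",
    "SDB",
)

# Aliases accepted when parsing annotations (R&K exports vary).
_STAGE_ALIASES = {
    "W": "W",
    "WAKE": "W",
    "S1": "S1",
    "S2": "S2",
    "S3": "S3",
    "S4": "S4",
    "R": "REM",
    "REM": "REM",
}


def normalize_stage(label: str) -> str | None:
    """Map a raw annotation label to a canonical stage, or ``None``.

    ``None`` is returned for scored-but-unused labels (e.g. movement
    time "MT"); callers drop those and count them.
    """
    return _STAGE_ALIASES.get(label.strip().upper())


def require_stage(label: str) -> str:
    stage = normalize_stage(label)
    if stage is None:
        raise ValueError(
            f"unknown sleep-stage label {label!r}; expected one of {sorted(_STAGE_ALIASES)}"
        )
    return stage
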