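"""Polarity-coded character states.

Binary morphological characters are coded against a hypothesised ancestor:
``0`` is the plesiomorphic (ancestral) condition, ``1`` the apomorphic
(derived) one.  Three qualified codes cover the realities of working from
published species descriptions: ``1?``/``0?`` mark a polarity argued from an
ambiguous description, and ``0*`` marks a taxon scored plesiomorphic whose
populations also show the derived condition (intraspecific variability).
"""

from __future__ import annotations

import enum


class StateCode(enum.Enum):
    """One cell of a polarity-coded character matrix."""

    PLESIOMORPHIC = "0"
    APOMORPHIC = "1"
    MISSING = "?"
    APOMORPHIC_UNCERTAIN = "1?"
    PLESIOMORPHIC_UNCERTAIN = "0?"
    PLESIOMORPHIC_VARIABLE = "0*"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def parse(cls, token: str) -> "StateCode":
        """Parse a serialized cell token; raises ``ValueError`` on anything
        outside the six recognised codes."""
        token = token.strip()
        try:
            return _BY_TOKEN[token]
        except KeyError:
            raise ValueError(f"unknown state token {token!r}") from None

    @property
    def is_uncertain(self) -> bool:
        """True for the four codes that are not a plain 0 or 1."""
        return self not in (StateCode.PLESIOMORPHIC, StateCode.APOMORPHIC)


_BY_TOKEN = {code.value: code for code in StateCode}

#: Resolved (post-policy) cell values: plain 0, plain 1, or missing.
RESOLVED = (StateCode.PLESIOMORPHIC, StateCode.APOMORPHIC, StateCode.MISSING)
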