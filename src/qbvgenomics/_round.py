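"""Half-up decimal rounding, used for all printed percentages and means."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (5 rounds up).

    Python's builtin ``round`` is banker's rounding; reported tables in this
    field conventionally round halves up, so all user-facing numbers go
    through this helper.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
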