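"""Closed-form polynomial values of the ribbon descriptors.

The distance descriptors of WNR(r, c, n) admit closed-form polynomial
expressions in (r, c, n), one family for the wide case (r <= c, r >= 2,
which also covers c = r - 1) and one for the narrow case c = r - 2
(r >= 3).  The degree and degree-sum descriptors have closed forms for
every r, c, n >= 1, obtained by weighting the closed-form edge partitions
with the descriptor functionals.

Everything rational is evaluated in exact integer/Fraction arithmetic
(the leading 1/30- and 1/60-type constants are exact); the Mostar
expressions carry parity terms in (-1)^n and absolute values.  Functions
raise :class:`OutOfDomainError` outside their validity window so callers
can fall back to the direct engines, which remain authoritative: any
disagreement between a closed form and direct computation is surfaced by
:func:`formula_discrepancy_report`.
"""

from __future__ import annotations

from fractions import Fraction

from wnrtools.degree_descriptors import (
    DESCRIPTOR_FUNCTIONS,
    table_degree_partition,
    table_degree_sum_partition,
)

__all__ = [
    "OutOfDomainError",
    "theorem1_domain",
    "theorem2_domain",
    "theorem1_values",
    "theorem2_values",
    "theorem3_values",
    "theorem4_values",
    "formula_discrepancy_report",
]


class OutOfDomainError(ValueError):
    """The requested (r, c, n) lies outside a closed form's validity window."""


def theorem1_domain(r: int, c: int, n: int) -> bool:
    """Wide-ribbon closed forms: r >= 2, n >= 1 and r <= c or c = r - 1."""
    return r >= 2 and n >= 1 and c >= 1 and (r <= c or c == r - 1)


def theorem2_domain(r: int, n: int) -> bool:
    """Narrow-ribbon closed forms for WNR(r, r-2, n): r >= 3, n >= 1."""
    return r >= 3 and n >= 1


def _as_int(x: Fraction, name: str) -> int:
    if x.denominator != 1:
        raise ArithmeticError(f"closed form for {name} is non-integer: {x}")
    return int(x)


def theorem1_values(r: int, c: int, n: int) -> dict[str, int]:
    """The eleven distance descriptors of WNR(r, c, n) for r <= c (r >= 2),
    also valid at c = r - 1.  Exact integers."""
    if not theorem1_domain(r, c, n):
        raise OutOfDomainError(
            f"wide-ribbon closed forms need r >= 2 and r <= c or c = r-1; "
            f"got (r, c, n) = ({r}, {c}, {n})"
        )
    F = Fraction
    out: dict[str, int] = {}

    out["W"] = _as_int(F(2, 15) * (
        r**4 * (15*n - 5*c + 15*c*n - 10) - r**5
        + r**3 * (30*n - 20*c + 80*c*n + 10*c**2*n)
        + r**2 * (80*c**3*n**3 + 240*c**2*n**3 + 30*c**2*n + 240*c*n**3
                  + 10*c*n + 5*c + 80*n**3 - 80*n + 40)
        + r * (160*c**3*n**3 + 320*c**2*n**3 + 160*c*n**3 - 70*c*n
               + 20*c + 30*n - 29)
        + 80*c**3*n**3 + 80*c**2*n**3 - 20*c**2*n - 5*c*n
    ), "W")

    out["We"] = _as_int(F(1, 30) * (
        r**4 * (135*n - 45*c + 135*c*n - 90) - 9*r**5
        + r**3 * (90*n - 150*c + 540*c*n + 90*c**2*n + 65)
        + r**2 * (720*c**3*n**3 + 2160*c**2*n**3 - 900*c**2*n**2 + 180*c**2*n
                  + 2160*c*n**3 - 1800*c*n**2 - 135*c*n + 165*c + 720*n**3
                  - 900*n**2 - 495*n + 300)
        + r * (960*c**3*n**3 + 1440*c**2*n**3 - 960*c**2*n**2 - 60*c**2*n
               - 480*c*n**2 + 240*c*n - 30*c - 480*n**3 + 480*n**2
               + 960*n - 596)
        + 320*c**3*n**3 - 240*c**2*n**2 - 120*c**2*n - 240*c*n**3
        + 240*c*n**2 + 40*c*n + 60*c + 80*n**3 - 60*n**2 - 530*n + 360
    ), "We")

    out["Wev"] = _as_int(F(1, 30) * (
        r**4 * (90*n - 30*c + 90*c*n - 60) - 6*r**5
        + r**3 * (120*n - 110*c + 420*c*n + 60*c**2*n + 20)
        + r**2 * (480*c**3*n**3 + 1440*c**2*n**3 - 300*c**2*n**2 + 150*c**2*n
                  + 1440*c*n**3 - 600*c*n**2 - 90*c*n + 75*c + 480*n**3
                  - 300*n**2 - 480*n + 240)
        + r * (800*c**3*n**3 + 1440*c**2*n**3 - 420*c**2*n**2 - 30*c**2*n
               + 480*c*n**3 - 360*c*n**2 - 200*c*n + 65*c - 160*n**3
               + 60*n**2 + 430*n - 284)
        + 320*c**3*n**3 + 160*c**2*n**3 - 120*c**2*n**2 - 100*c**2*n
        - 160*c*n**3 + 60*c*n**2 + 50*c*n - 120*n + 90
    ), "Wev")

    out["Szv"] = _as_int(F(1, 3) * (
        r**4 * (6*n - 3*c + 6*c*n - 7)
        + r**3 * (48*c**3*n**3 + 144*c**2*n**3 + 144*c*n**3 + 28*c*n
                  - 22*c + 48*n**3 + 4*n - 8)
        + r**2 * (128*c**3*n**3 + 4*c**3*n + 240*c**2*n**3 + 36*c**2*n
                  - 12*c**2 + 96*c*n**3 + 48*c*n - 16*n**3 - 8*n + 31)
        + r * (112*c**3*n**3 + 4*c**3*n + 80*c**2*n**3 - 8*c**2*n + 12*c**2
               - 32*c*n**3 - 70*c*n + 49*c - 52*n + 26)
        + 32*c**3*n**3 - 16*c**2*n**3 + 4*c**2*n + 22*c*n - 24*c + 48*n - 42
    ), "Szv")

    out["Sze"] = _as_int(F(1, 30) * (
        r**4 * (195*n - 60*c + 195*c*n - 160) - 3*r**5
        + r**3 * (1080*c**3*n**3 + 3240*c**2*n**3 - 1260*c**2*n**2
                  + 210*c**2*n + 3240*c*n**3 - 2520*c*n**2 + 1600*c*n
                  - 440*c + 1080*n**3 - 1260*n**2 + 850*n - 235)
        + r**2 * (2160*c**3*n**3 - 180*c**3*n**2 + 60*c**3*n + 3240*c**2*n**3
                  - 2820*c**2*n**2 + 990*c**2*n - 240*c**2 - 2220*c*n**2
                  + 1065*c*n - 60*c - 1080*n**3 + 420*n**2 - 885*n + 580)
        + r * (1440*c**3*n**3 - 120*c**3*n**2 + 80*c**3*n - 780*c**2*n**2
               - 390*c**2*n + 180*c**2 - 1080*c*n**3 + 1860*c*n**2
               - 2160*c*n + 980*c + 360*n**3 + 900*n**2 - 820*n + 448)
        + 320*c**3*n**3 - 480*c**2*n**3 + 240*c**2*n**2 - 360*c**2*n
        + 60*c**2 + 240*c*n**3 + 480*c*n**2 + 40*c*n - 300*c - 40*n**3
        - 300*n**2 + 340*n - 360
    ), "Sze")

    out["Szev"] = _as_int(F(1, 60) * (
        r**4 * (220*n - 85*c + 220*c*n - 200) - 2*r**5
        + r**3 * (1440*c**3*n**3 + 4320*c**2*n**3 - 840*c**2*n**2
                  + 140*c**2*n + 4320*c*n**3 - 1680*c*n**2 + 1340*c*n
                  - 580*c + 1440*n**3 - 840*n**2 + 480*n - 170)
        + r**2 * (3360*c**3*n**3 - 120*c**3*n**2 + 100*c**3*n
                  + 5760*c**2*n**3 - 2160*c**2*n**2 + 1200*c**2*n - 330*c**2
                  + 1440*c*n**3 - 2040*c*n**2 + 1240*c*n + 55*c - 960*n**3
                  - 640*n + 800)
        + r * (2560*c**3*n**3 - 120*c**3*n**2 + 100*c**3*n + 960*c**2*n**3
               - 960*c**2*n**2 - 440*c**2*n + 330*c**2 - 1440*c*n**3
               + 840*c*n**2 - 2680*c*n + 1330*c + 160*n**3 + 600*n**2
               - 1300*n + 592)
        + 640*c**3*n**3 - 640*c**2*n**3 + 240*c**2*n**2 - 200*c**2*n
        + 160*c*n**3 + 600*c*n**2 + 460*c*n - 720*c + 1080*n - 1020
    ), "Szev")

    out["PI"] = _as_int(F(2, 3) * (
        r**3
        + r**2 * (54*c**2*n**2 + 108*c*n**2 - 30*c*n + 3*c + 54*n**2
                  - 30*n + 9)
        + r * (72*c**2*n**2 - 3*c**2*n + 36*c*n**2 - 36*c*n + 3*c - 36*n**2
               + 3*n - 7)
        + 24*c**2*n**2 - 24*c*n**2 + 6*c*n - 6*c + 6*n**2 + 15*n - 6
    ), "PI")

    out["S"] = _as_int(F(2, 15) * (
        r**4 * (90*n - 30*c + 90*c*n - 60) - 6*r**5
        + r**3 * (120*n - 110*c + 420*c*n + 60*c**2*n + 20)
        + r**2 * (480*c**3*n**3 + 1440*c**2*n**3 - 120*c**2*n**2
                  + 150*c**2*n + 1440*c*n**3 - 240*c*n**2 - 120*c*n + 75*c
                  + 480*n**3 - 120*n**2 - 510*n + 240)
        + r * (800*c**3*n**3 + 1440*c**2*n**3 - 120*c**2*n**2 - 30*c**2*n
               + 480*c*n**3 - 120*c*n**2 - 230*c*n + 65*c - 160*n**3
               + 430*n - 284)
        + 320*c**3*n**3 + 160*c**2*n**3 - 100*c**2*n - 160*c*n**3
        + 50*c*n - 120*n + 90
    ), "S")

    out["Gut"] = _as_int(F(1, 15) * (
        r**4 * (270*n - 90*c + 270*c*n - 180) - 18*r**5
        + r**3 * (180*n - 300*c + 1080*c*n + 180*c**2*n + 140)
        + r**2 * (1440*c**3*n**3 + 4320*c**2*n**3 - 720*c**2*n**2
                  + 360*c**2*n + 4320*c*n**3 - 1440*c*n**2 - 750*c*n
                  + 360*c + 1440*n**3 - 720*n**2 - 1470*n + 705)
        + r * (1920*c**3*n**3 + 2880*c**2*n**3 - 480*c**2*n**2 - 150*c**2*n
               - 240*c*n**2 - 30*c - 960*n**3 + 240*n**2 + 2010*n - 1262)
        + 640*c**3*n**3 - 240*c**2*n - 480*c*n**3 + 140*c*n + 60*c
        + 160*n**3 - 910*n + 660
    ), "Gut")

    sgn_odd = 1 - (-1) ** n   # 2 for odd n, 0 for even n
    sgn_even = 1 + (-1) ** n  # 0 for odd n, 2 for even n

    out["Mov"] = _as_int(F(
        r**2 * (12*c**2*n**2 + 24*c*n**2 - 4*c*n + 6*c + 12*n**2 - 4*n + 6)
        - 2*r**4
        + r * (20*c**2*n**2 + 16*c*n**2 - 4*c*n - 10*c - 4*n**2 - 8)
        + 8*c**2*n**2 - 8*c**2 - 4*c*n**2 - 16*c - 4
        + 2 * sgn_odd * (r + c + 1) * abs(r**2 - 2*c - 2)
        + 2 * sgn_even * (r + c + 1) * abs(2*c - r**2 + 2)
    ), "Mov")

    out["Moe"] = _as_int(F(1, 6) * (
        4*r**3 - 18*r**4
        + r**2 * (108*c**2*n**2 + 216*c*n**2 - 36*c*n + 48*c + 108*n**2
                  - 36*n + 42)
        + r * (144*c**2*n**2 + 72*c*n**2 - 24*c*n - 84*c - 72*n**2
               + 12*n - 40)
        + 48*c**2*n**2 - 60*c**2 - 48*c*n**2 - 120*c + 12*n**2 - 60
    ) + (
        sgn_odd * (r + c + 1) * abs(3*r**2 - r - 5*c - 5)
        + sgn_even * (r + c + 1) * abs(r - 3*r**2 + 5*c + 5)
    ), "Moe")

    return out


def theorem2_values(r: int, n: int) -> dict[str, int]:
    """The eleven distance descriptors of the narrow ribbon WNR(r, r-2, n),
    r >= 3.  Exact integers."""
    if not theorem2_domain(r, n):
        raise OutOfDomainError(
            f"narrow-ribbon closed forms need r >= 3, n >= 1; got ({r}, {n})"
        )
    F = Fraction
    out: dict[str, int] = {}

    out["W"] = _as_int(F(2, 15) * (
        r**5 * (80*n**3 + 25*n - 6) - r**4 * (80*n**3 - 55*n + 20)
        - r**3 * (320*n**3 + 200*n - 45) + r**2 * (320*n**3 + 50*n - 70)
        + r * (320*n**3 - 235*n + 351) - 320*n**3 + 410*n - 360
    ), "W")

    out["We"] = _as_int(F(1, 30) * (
        r**5 * (720*n**3 + 225*n - 54)
        - r**4 * (1200*n**3 + 900*n**2 - 225*n + 150)
        - r**3 * (1840*n**3 - 840*n**2 + 1545*n - 530)
        + r**2 * (3120*n**3 + 2220*n**2 + 1635*n - 840)
        + r * (1200*n**3 - 1200*n**2 - 2360*n + 2164)
        - 2000*n**3 - 1500*n**2 + 2030*n - 1920
    ), "We")

    out["Wev"] = _as_int(F(1, 30) * (
        r**5 * (480*n**3 + 150*n - 36)
        - r**4 * (640*n**3 + 300*n**2 - 240*n + 110)
        - r**3 * (1600*n**3 - 180*n**2 + 1200*n - 315)
        + r**2 * (2080*n**3 + 900*n**2 + 720*n - 445)
        + r * (1280*n**3 - 360*n**2 - 1240*n + 1656)
        - 1600*n**3 - 600*n**2 + 1780*n - 1650
    ), "Wev")

    out["Szv"] = _as_int(F(1, 3) * (
        48*n**3*r**6 - r**5 * (16*n**3 - 10*n + 3)
        - r**4 * (272*n**3 - 38*n + 35) + r**3 * (64*n**3 - 60*n + 12)
        + r**2 * (512*n**3 - 362*n + 368) - r * (64*n**3 - 654*n + 606)
        - 320*n**3 - 268*n + 258
    ), "Szv")

    out["Sze"] = _as_int(F(1, 30) * (
        1080*n**3*r**6 - r**5 * (1080*n**3 + 1440*n**2 - 465*n + 63)
        - r**4 * (5040*n**3 - 300*n**2 - 1635*n + 720)
        + r**3 * (3560*n**3 + 7140*n**2 - 4375*n + 165)
        + r**2 * (8400*n**3 - 2520*n**2 - 6015*n + 6720)
        - r * (3000*n**3 + 7380*n**2 - 15020*n + 10332)
        - 5000*n**3 + 2100*n**2 - 6940*n + 4320
    ), "Sze")

    out["Szev"] = _as_int(F(1, 60) * (
        1440*n**3*r**6 - r**5 * (960*n**3 + 960*n**2 - 460*n + 87)
        - r**4 * (7520*n**3 + 120*n**2 - 1500*n + 940)
        + r**3 * (3520*n**3 + 5040*n**2 - 3960*n + 595)
        + r**2 * (13280*n**3 - 600*n**2 - 8520*n + 8800)
        - r * (3200*n**3 + 6240*n**2 - 19440*n + 14908)
        - 8000*n**3 + 1680*n**2 - 8560*n + 6420
    ), "Szev")

    out["PI"] = _as_int(F(2, 3) * (
        54*n**2*r**4 - r**3 * (36*n**2 + 33*n - 4)
        - r**2 * (174*n**2 - 12) + r * (60*n**2 + 93*n - 37)
        + 150*n**2 - 21*n + 18
    ), "PI")

    out["S"] = _as_int(F(2, 15) * (
        r**5 * (480*n**3 + 150*n - 36)
        - r**4 * (640*n**3 + 120*n**2 - 240*n + 110)
        - r**3 * (1600*n**3 - 120*n**2 + 1230*n - 315)
        + r**2 * (2080*n**3 + 240*n**2 + 720*n - 445)
        + r * (1280*n**3 - 240*n**2 - 1180*n + 1656)
        - 1600*n**3 + 1780*n - 1650
    ), "S")

    out["Gut"] = _as_int(F(1, 15) * (
        r**5 * (1440*n**3 + 450*n - 108)
        - r**4 * (2400*n**3 + 720*n**2 - 450*n + 300)
        - r**3 * (3680*n**3 - 960*n**2 + 3600*n - 1100)
        + r**2 * (6240*n**3 + 960*n**2 + 3330*n - 1545)
        + r * (2400*n**3 - 1200*n**2 - 3490*n + 3958)
        - 4000*n**3 + 3850*n - 3660
    ), "Gut")

    sgn_odd = 1 - (-1) ** n
    sgn_even = 1 + (-1) ** n

    out["Mov"] = (
        r**4 * (12*n**2 - 10) - r**3 * (4*n**2 + 4*n - 30)
        - r**2 * (44*n**2 + 28) + r * (8*n**2 + 8*n + 24) + 40*n**2 - 20
        + 4 * r * sgn_odd * sum(
            abs(3*r**2 - 4*i*r - 2*r - 2) for i in range(1, r - 1))
        + 4 * r * sgn_even * sum(
            abs(r**2 - 4*i*r - 2*r + 2) for i in range(1, r - 1))
    )

    out["Moe"] = _as_int(F(1, 6) * (
        r**4 * (108*n**2 - 90) - r**3 * (72*n**2 + 36*n - 292)
        - r**2 * (348*n**2 - 12*n + 306) + r * (120*n**2 + 60*n + 224)
        + 300*n**2 - 168
    ) + (
        2 * r * sgn_odd * sum(
            abs(2*i - 8*r - 12*i*r + 9*r**2 - 4) for i in range(1, r - 1))
        + 2 * r * sgn_even * sum(
            abs(2*i - 6*r - 12*i*r + 3*r**2 + 6) for i in range(1, r - 1))
    ), "Moe")

    return out


def theorem3_values(r: int, c: int, n: int) -> dict[str, float]:
    """Closed-form degree descriptors of WNR(r, c, n): the Table-3 edge
    partition weighted by each functional.  Valid for all r, c, n >= 1."""
    part = table_degree_partition(r, c, n)
    return {
        name: sum(cnt * fn(s, t) for (s, t), cnt in sorted(part.items()))
        for name, fn in DESCRIPTOR_FUNCTIONS.items()
    }


def theorem4_values(r: int, c: int, n: int) -> dict[str, float]:
    """Closed-form degree-sum descriptors of WNR(r, c, n).

    Meaningful for r, c, n >= 2 only; at n = 1 several closed-form bond
    counts are negative and the values disagree with direct computation
    on the actual skeleton (reported, not hidden).
    """
    part = table_degree_sum_partition(r, c, n)
    return {
        name: sum(cnt * fn(s, t) for (s, t), cnt in sorted(part.items()))
        for name, fn in DESCRIPTOR_FUNCTIONS.items()
    }


def formula_discrepancy_report(
    closed: dict[str, float], direct: dict[str, float], rtol: float = 0.0
) -> list[dict]:
    """Compare closed-form against direct values descriptor by descriptor.

    Returns rows (descriptor, closed, direct, match).  ``rtol = 0``
    demands exact equality (integer descriptors); use e.g. 1e-9 for the
    surd-bearing degree functionals.
    """
    rows = []
    for name, dv in direct.items():
        cv = closed.get(name)
        if cv is None:
            continue
        if rtol == 0.0:
            ok = cv == dv
        else:
            ok = abs(cv - dv) <= rtol * max(1.0, abs(dv))
        rows.append({"descriptor": name, "closed_form": cv,
                     "direct": dv, "match": bool(ok)})
    return rows
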