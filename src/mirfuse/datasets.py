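"""Published reference datasets from a maize carpel-fusion ovary study.

Deep-sequencing summary tables for ovaries with incompletely (IFC) versus
completely fused carpels (CFC), embedded as plain data so the pipeline's
decision rules can be exercised against published numbers without any
download:

* ``DE_KNOWN_MIRNAS`` - the 20 differentially expressed known miRNAs with
  mean normalized expression (NE) per phenotype, t-test p-value and printed
  regulation direction (up = higher in IFC).
* ``DEGRADOME_TARGETS`` - degradome-identified target transcripts of the
  differentially expressed known miRNAs, with confidence class section,
  cleavage register, per-condition peak category and TPB.
* ``HORMONE_CORRELATIONS`` - Pearson r of eight miRNA families and eight of
  their targets against six phytohormone series (n = 8), with printed
  significance flags.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DERow:
    family: str
    name: str
    ne_ifc: float
    ne_cfc: float
    p: float
    direction: str


DE_KNOWN_MIRNAS: tuple[DERow, ...] = (
    DERow("miR156", "ata-miR156b-3p_1ss6TC", 16.21, 7.67, 0.038, "up"),
    DERow("miR156", "zma-miR156l-3p", 22.34, 3.71, 0.000, "up"),
    DERow("miR159", "zma-miR159a-3p", 147.48, 406.41, 0.000, "down"),
    DERow("miR159", "zma-miR159c-3p_L-1R-1", 928.11, 471.01, 0.000, "up"),
    DERow("miR160", "osa-miR160a-5p_L+1", 1.33, 8.37, 0.040, "down"),
    DERow("miR160", "zma-miR160f-5p_1ss21GA", 89.55, 144.19, 0.010, "down"),
    DERow("miR164", "osa-miR164d_R+1_1ss21TA", 0.00, 5.16, 0.049, "down"),
    DERow("miR166", "zma-miR166j-3p", 507.86, 838.61, 0.000, "down"),
    DERow("miR168", "zma-miR168a-5p", 211.24, 359.37, 0.000, "down"),
    DERow("miR169", "zma-miR169p-5p", 31.30, 117.39, 0.000, "down"),
    DERow("miR171", "zma-miR171d-5p", 173.58, 67.98, 0.000, "up"),
    DERow("miR171", "osa-miR171i-5p", 21.04, 9.64, 0.015, "up"),
    DERow("miR171", "gma-miR171m_1ss21AC", 338.41, 518.29, 0.000, "down"),
    DERow("miR172", "zma-miR172e", 0.42, 11.52, 0.003, "down"),
    DERow("miR390", "zma-miR390a-5p", 200.96, 391.99, 0.000, "down"),
    DERow("miR393", "zma-miR393b-5p_R-1", 4.83, 19.92, 0.007, "down"),
    DERow("miR393", "zma-miR393c-3p_L-1", 0.21, 6.31, 0.026, "down"),
    DERow("miR396", "zma-miR396a-5p", 96.75, 165.23, 0.002, "down"),
    DERow("miR399", "zma-miR399c-5p", 54.47, 91.18, 0.025, "down"),
    DERow("miR827", "zma-miR827-5p_L+1", 473.66, 878.55, 0.000, "down"),
)


@dataclass(frozen=True)
class TargetRow:
    cls: str            # published class section: I, II, III
    family: str
    transcripts: str    # comma-separated transcript ids as printed
    annotation: str
    tf_family: str
    cleavage_position: int  # cleavage register within the miRNA
    category_ifc: int
    category_cfc: int
    tpb_ifc: int
    tpb_cfc: int

    @property
    def gene(self) -> str:
        """Gene-level id (first transcript id without the _Txx suffix)."""
        first = self.transcripts.split(",")[0].strip()
        return first.split("_T")[0]


DEGRADOME_TARGETS: tuple[TargetRow, ...] = (
    # Class I
    TargetRow("I", "miR159", "GRMZM2G089361_T01", "TCP family transcription factor", "TCP", 10, 0, 0, 473, 1199),
    TargetRow("I", "miR159", "3030GRMZM2G020805_T01", "TCP family transcription factor", "TCP", 10, 0, 0, 2542, 2458),
    TargetRow("I", "miR159", "GRMZM2G028054_T01, T02, T03", "myb domain protein", "MYB", 10, 0, 0, 709, 580),
    TargetRow("I", "miR159", "GRMZM2G015037_T01, T02", "TCP family transcription factor", "TCP", 10, 0, 0, 473, 929),
    TargetRow("I", "miR159", "AC217264.3_FGT005", "myb domain protein", "MYB", 10, 0, 0, 650, 240),
    TargetRow("I", "miR160", "GRMZM2G159399_T01", "auxin response factor", "ARF", 10, 0, 0, 52379, 66723),
    TargetRow("I", "miR160", "GRMZM2G005284_T01", "auxin response factor", "ARF", 10, 1, 0, 177, 120),
    TargetRow("I", "miR164", "GRMZM2G063522_T01", "NAC domain containing protein", "NAC", 10, 0, 0, 9932, 12170),
    TargetRow("I", "miR166", "GRMZM2G038198_T01", "Homeobox-leucine zipper protein", "", 10, 0, 0, 5819, 7554),
    TargetRow("I", "miR166", "AC187157.4_FGT005", "Homeobox-leucine zipper protein", "", 10, 0, 0, 709, 899),
    TargetRow("I", "miR169", "GRMZM2G040349_T01, T02", "nuclear factor Y", "NF-YA", 10, 0, 0, 207, 150),
    TargetRow("I", "miR169", "GRMZM2G000686_T01, T02, T03, T04, T05, T06, T08", "nuclear factor Y", "NF-YA", 10, 0, 0, 177, 187),
    TargetRow("I", "miR172", "GRMZM2G076602_T01", "DNA-binding protein", "AP2", 10, 0, 0, 1064, 480),
    TargetRow("I", "miR393", "GRMZM2G137451_T01,T02", "auxin signaling F-box / AFB", "", 10, 0, 0, 276, 520),
    TargetRow("I", "miR396", "GRMZM2G033612_T02", "growth-regulating factor", "GRF", 11, 0, 0, 10819, 17865),
    TargetRow("I", "miR396", "GRMZM2G018414_T01, T02", "growth-regulating factor", "GRF", 11, 0, 0, 532, 1529),
    TargetRow("I", "miR396", "GRMZM2G099862_T01, T02, T03, T04", "growth-regulating factor", "GRF", 11, 0, 0, 665, 689),
    TargetRow("I", "miR396", "GRMZM2G041223_T01", "growth-regulating factor", "GRF", 11, 0, 0, 335, 560),
    TargetRow("I", "miR396", "GRMZM2G034876_T01, T02, T03", "growth-regulating factor", "GRF", 11, 0, 0, 355, 380),
    TargetRow("I", "miR396", "GRMZM2G129147_T01, T02", "growth-regulating factor", "GRF", 11, 0, 0, 2256, 2987),
    # Class II
    TargetRow("II", "miR159", "GRMZM2G004090_T01", "myb domain protein", "MYB", 10, 2, 0, 118, 210),
    TargetRow("II", "miR159", "GRMZM2G028054_T01, T02, T03", "myb domain protein", "MYB", 10, 2, 2, 117, 240),
    TargetRow("II", "miR160", "GRMZM2G159399_T01", "auxin response factor", "ARF", 10, 2, 2, 946, 1079),
    TargetRow("II", "miR166", "GRMZM2G552083_T01", "Homeobox-leucine zipper protein", "", 10, 2, 0, 25, 188),
    TargetRow("II", "miR166", "GRMZM2G123644_T01", "agenet-containing protein", "", 10, 2, 2, 25, 188),
    TargetRow("II", "miR166", "GRMZM2G336718_T01", "agenet-containing protein", "", 10, 2, 2, 25, 188),
    TargetRow("II", "miR171", "GRMZM2G051785_T01", "GRAS transcription factor", "GRAS", 10, 0, 2, 0, 180),
    TargetRow("II", "miR171", "GRMZM2G110579_T01", "GRAS transcription factor", "GRAS", 10, 2, 2, 635, 555),
    TargetRow("II", "miR171", "GRMZM2G037792_T01", "GRAS transcription factor", "GRAS", 10, 2, 2, 315, 360),
    TargetRow("II", "miR171", "GRMZM5G825321_T01, T02", "GRAS transcription factor", "GRAS", 10, 2, 2, 296, 360),
    TargetRow("II", "miR393", "GRMZM5G848945_T02", "auxin signaling F-box / AFB", "", 10, 2, 2, 276, 520),
    TargetRow("II", "miR396", "GRMZM2G067743_T01, T03", "growth-regulating factor", "GRF", 11, 2, 0, 39, 160),
    TargetRow("II", "miR396", "GRMZM2G067743_T02", "growth-regulating factor", "GRF", 11, 1, 0, 39, 160),
    # Class III
    TargetRow("III", "miR159", "GRMZM2G113073_T01", "P21-Rho-binding domain", "", 10, 2, 4, 177, 60),
    TargetRow("III", "miR159", "GRMZM2G127720_T01", "-", "", 10, 4, 0, 59, 0),
    TargetRow("III", "miR159", "AC217264.3_FGT005", "myb domain protein", "MYB", 10, 0, 4, 0, 60),
    TargetRow("III", "miR159", "GRMZM2G070523_T01, T02, T03", "myb domain protein", "MYB", 10, 4, 0, 20, 0),
    TargetRow("III", "miR166", "GRMZM2G003509_T01, T02", "Homeobox-leucine zipper protein", "HD-ZIP", 10, 3, 2, 25, 231),
    TargetRow("III", "miR169", "GRMZM2G037630_T01", "nuclear factor Y, subunit A6", "NF-YA", 10, 4, 0, 59, 120),
    TargetRow("III", "miR171", "GRMZM2G000039_T01", "SIT4 phosphatase-associated protein", "", 10, 3, 4, 20, 40),
    TargetRow("III", "miR172", "GRMZM5G856084_T01", "DNAJ heat shock family protein", "", 10, 4, 0, 59, 0),
    TargetRow("III", "miR390", "GRMZM2G121820_T01", "Leucine-rich repeat family protein", "", 10, 0, 4, 0, 20),
    TargetRow("III", "miR390", "GRMZM5G815009_T01, T02", "Leucine-rich repeat family protein", "", 10, 0, 4, 0, 20),
    TargetRow("III", "miR396", "GRMZM2G024293_T01, T03", "P-loop nucleoside triphosphate hydrolases", "", 10, 3, 3, 59, 90),
)


@dataclass(frozen=True)
class CorrRow:
    series_id: str
    kind: str  # "mirna" or "target"
    r: dict

    def flag(self, hormone: str) -> str:
        return self.r[hormone][1]


def _c(r: float, flag: str = "ns") -> tuple[float, str]:
    return (r, flag)


HORMONE_CORRELATIONS: tuple[CorrRow, ...] = (
    CorrRow("miR159a-d, f, j, k", "mirna", {"IAA": _c(0.73, "*"), "ZR+iPA": _c(-0.77, "*"), "GA": _c(-0.88, "**"), "BR": _c(-0.93, "**"), "JA": _c(-0.94, "**"), "ABA": _c(-0.29)}),
    CorrRow("miR160a-e, g", "mirna", {"IAA": _c(0.61, "*"), "ZR+iPA": _c(0.55), "GA": _c(0.34), "BR": _c(-0.05), "JA": _c(0.04), "ABA": _c(0.93, "**")}),
    CorrRow("miR164a-d, f, g", "mirna", {"IAA": _c(0.28), "ZR+iPA": _c(0.55), "GA": _c(0.39), "BR": _c(0.39), "JA": _c(0.44), "ABA": _c(0.79, "**")}),
    CorrRow("miR166j, k, n", "mirna", {"IAA": _c(0.31), "ZR+iPA": _c(0.72, "*"), "GA": _c(0.57), "BR": _c(0.26), "JA": _c(0.34), "ABA": _c(0.91, "**")}),
    CorrRow("miR169c, p, r", "mirna", {"IAA": _c(0.32), "ZR+iPA": _c(0.74, "*"), "GA": _c(0.55), "BR": _c(0.26), "JA": _c(0.34), "ABA": _c(0.99, "**")}),
    CorrRow("miR172e", "mirna", {"IAA": _c(0.45), "ZR+iPA": _c(0.70, "*"), "GA": _c(0.55), "BR": _c(0.06), "JA": _c(0.16), "ABA": _c(0.93, "**")}),
    CorrRow("miR393a-c", "mirna", {"IAA": _c(0.47), "ZR+iPA": _c(0.68, "*"), "GA": _c(0.52), "BR": _c(0.06), "JA": _c(0.14), "ABA": _c(0.91, "**")}),
    CorrRow("miR396a, b, e, f", "mirna", {"IAA": _c(-0.38), "ZR+iPA": _c(0.88, "**"), "GA": _c(0.77, "*"), "BR": _c(0.80, "**"), "JA": _c(0.79, "**"), "ABA": _c(0.68, "*")}),
    CorrRow("T-miR159c (TCP) GRMZM2G089361_T01", "target", {"IAA": _c(-0.79, "**"), "ZR+iPA": _c(0.54), "GA": _c(0.69, "*"), "BR": _c(0.94, "**"), "JA": _c(0.94, "**"), "ABA": _c(0.07)}),
    CorrRow("T-miR160f (ARF) GRMZM2G005284_T01", "target", {"IAA": _c(-0.11), "ZR+iPA": _c(-0.51), "GA": _c(-0.36), "BR": _c(-0.51), "JA": _c(-0.52), "ABA": _c(-0.63, "*")}),
    CorrRow("T-miR164d (NAC) GRMZM2G063522_T01", "target", {"IAA": _c(-0.20), "ZR+iPA": _c(-0.77, "*"), "GA": _c(-0.62, "*"), "BR": _c(-0.43), "JA": _c(-0.49), "ABA": _c(-0.88, "**")}),
    CorrRow("T-miR166j (HB) AC187157.4_FGT005", "target", {"IAA": _c(-0.18), "ZR+iPA": _c(-0.76, "*"), "GA": _c(-0.61, "*"), "BR": _c(-0.48), "JA": _c(-0.53), "ABA": _c(-0.89, "**")}),
    CorrRow("T-miR169p (NF-YA) GRMZM2G040349_T01,T02", "target", {"IAA": _c(0.06), "ZR+iPA": _c(-0.66, "*"), "GA": _c(-0.71, "*"), "BR": _c(-0.52), "JA": _c(-0.64, "*"), "ABA": _c(-0.70, "*")}),
    CorrRow("T-miR172e (AP2) GRMZM2G076602_T01", "target", {"IAA": _c(-0.48), "ZR+iPA": _c(-0.46), "GA": _c(-0.24), "BR": _c(-0.14), "JA": _c(-0.20), "ABA": _c(-0.87, "**")}),
    CorrRow("T-miR393b (AFB) GRMZM2G137451_T01, T02", "target", {"IAA": _c(0.22), "ZR+iPA": _c(-0.80, "**"), "GA": _c(-0.83, "**"), "BR": _c(-0.61), "JA": _c(-0.64, "*"), "ABA": _c(-0.46)}),
    CorrRow("T-miR396a (GRF) GRMZM2G033612_T02", "target", {"IAA": _c(0.18), "ZR+iPA": _c(-0.84, "**"), "GA": _c(-0.85, "**"), "BR": _c(-0.74, "*"), "JA": _c(-0.82, "**"), "ABA": _c(-0.73, "*")}),
)
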