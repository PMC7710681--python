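"""Packaged study data: the 39-character matrix for the 12 examined
*Laophontodes* species, the reference cladogram, and the diagnostic key.

Taxon labels are genus-abbreviated epithets (``L_sarsi``); ``TAXON_NAMES``
maps them back to full binomina with authorities.  Cells are transcribed
verbatim, including the qualified codes ``?``, ``1?``, ``0?`` and ``0*`` and
the convergence annotations (bold cells of the source table).
"""

from __future__ import annotations

from .key import DichotomousKey, Lead
from .matrix import CharacterDefinition, CharacterMatrix
from .states import StateCode
from .tree import Cladogram, parse_tree

__all__ = [
    "TAXA",
    "TAXON_NAMES",
    "laophontodes_matrix",
    "reference_cladogram",
    "laophontodes_key",
    "ripples_character",
]

#: Column order of the character table.
TAXA = [
    "L_sarsi",
    "L_scottorum",
    "L_volkerlehmanskii",
    "L_georgei",
    "L_gertraudae",
    "L_spongiosus",
    "L_mourois",
    "L_typicus",
    "L_monsmaris",
    "L_macclintocki",
    "L_sabinegeorgeae",
    "L_whitsoni",
]

TAXON_NAMES = {
    "L_sarsi": "Laophontodes sarsi George, 2018",
    "L_scottorum": "Laophontodes scottorum George, 2018",
    "L_volkerlehmanskii": "Laophontodes volkerlehmanskii sp. nov.",
    "L_georgei": "Laophontodes georgei Lee & Huys, 2019",
    "L_gertraudae": "Laophontodes gertraudae George, 2018",
    "L_spongiosus": "Laophontodes spongiosus Schizas & Shirley, 1994",
    "L_mourois": "Laophontodes mourois Arroyo, George, Benito & Maldonado, 2003",
    "L_typicus": "Laophontodes typicus T. Scott, 1894",
    "L_monsmaris": "Laophontodes monsmaris George, 2018",
    "L_macclintocki": "Laophontodes macclintocki Schizas & Shirley, 1994",
    "L_sabinegeorgeae": "Laophontodes sabinegeorgeae George, 2018",
    "L_whitsoni": "Laophontodes whitsoni T. Scott, 1912",
}

# (id, apomorphic description, plesiomorphic description, row of 12 cell codes)
_CHARACTERS: list[tuple[int, str, str, str]] = [
    (1, "A2 exopod represented by tiny seta",
     "A2 exopod with 1 small, knob-like segment bearing 1 small seta",
     "1 1 1 1 1 1 1 1 1 1 1 1"),
    (2, "A1 male 6-segmented, chirocer", "A1 male 7-segmented, subchirocer",
     "? 1 1 1 1 1? 1 1 1 0? 0 0"),
    (3, "P4 female enp-2 lacking outer seta", "outer seta present",
     "1 1 1 1 1 1 1 1 1 0 0 0*"),
    (4, "P3exp-3 with at most 1 inner seta", "P3exp-3 with 2 inner setae",
     "1 1 1 1 1 1 1 1 0 1 0 0"),
    (5, "P4exp-3 with at most 1 inner seta", "P4exp-3 with 2 inner setae",
     "1 1 1 1 1 1 1 1 0 1 0 0"),
    (6, "P2exp-2 lacking inner seta", "inner seta present",
     "1 1 1 1 1 1 1 1 0 0 0 0"),
    (7, "P3exp-2 lacking inner seta", "inner seta present",
     "1 1 1 1 1 1 1 1 0 0 0 0"),
    (8, "P2exp-3 lacking inner seta", "inner seta present",
     "1 1 1 1 1 1 0 0 0 0 0 0"),
    (9, "P4exp-3 inner apical seta trimmed down, flexible",
     "seta almost identical with outer apical element",
     "1 1 1 1 0 0 0 0 0 0 0 0"),
    (10, "P2exp-3 inner apical seta trimmed down, flexible",
     "seta almost identical with outer apical element",
     "1 1 1 0 0 0 0 0 0 0 0 0"),
    (11, "P3exp-3 inner apical seta trimmed down, flexible",
     "seta almost identical with outer apical element",
     "1 1 1 0 0 0 0 0 0 0 0 0"),
    (12, "P2exp-3 down-trimmed inner apical seta bare", "seta biplumose",
     "1 1 0 0 0 0 0 0 0 0 0 0"),
    (13, "P3exp-3 down-trimmed inner apical seta bare", "seta biplumose",
     "1 1 0 0 0 0 0 0 0 0 0 0"),
    (14, "P4exp-3 down-trimmed inner apical seta bare", "seta biplumose",
     "1 1 0 0 0 0 0 0 0 0 0 0"),
    (15, "P5 female inner baseoendopodal seta of fish-bone aspect",
     "seta bipinnate",
     "1 0 0 0 0 0 0 0 0 0 0 0"),
    (16, "Body flattened", "body cylindrical",
     "0 1 0 0 0 0 0 0 0 0 0 0"),
    (17, "Body somites laterally extended", "somites not extended",
     "0 1 0 0 0 1 0 0 0 0 0 0"),
    (18, "Anal operculum: posterior margin strongly serrated",
     "posterior margin with spinules",
     "0 0 1 0 0 0 0 0 0 0 0 0"),
    (19, "Furcal tube pore long, displaced subapically",
     "tube pore small, near furcal base",
     "0 0 1 0 0 0 0 0 0 0 0 0"),
    (20, "P1 inner basal seta strongly diminished in size",
     "seta of moderate length",
     "0 0 1 0 0 0 0 0 0 0 0 0"),
    (21, "P1 outer basal seta with STE", "seta lacking STE",
     "0 0 1 0 0 0 0 0 0 0 0 0"),
    (22, "P1exp-1 outer seta with STE", "seta lacking STE",
     "0 0 1 0 0 0 0 0 0 0 0 0"),
    (23, "P5 male exopod: subapical outer seta with STE", "seta lacking STE",
     "0 0 1 0 0 0 0 0 0 0 0 0"),
    (24, "P1enp-2 apical long seta lost geniculation", "seta geniculated",
     "0 0 0 1 0 0 0 0 0 0 0 0"),
    (25, "P4 endopod 1-segmented", "P4 endopod 2-segmented",
     "0 0 0 1 0 0 0 0 0 0 0 0"),
    (26, "P4enp-2 lacking inner seta", "inner seta present",
     "0 0 0 0 1 0 0 0 0 0 0 0*"),
    (27, "Abdominal somites except telson dorsally with H-like cuticular "
     "structures", "such structures absent",
     "0 0 0 0 0 1 0 0 0 0 0 0"),
    (28, "P2exp-3 inner apical seta bare", "seta biplumose",
     "0 0 0 0 0 0 1 1 0 0 0 0"),
    (29, "P3 male enp-3 bulged out on its inner margin", "margin straight",
     "0 0 0 0 0 0 1 0 0 0 0 0"),
    (30, "Mxp lacking tiny seta accompanying claw", "tiny seta present",
     "0 0 0 ? 0 0 0 1 0 1 0 0"),
    (31, "Mxp extremely strengthened", "mxp of moderate size",
     "0 0 0 0 0 0 0 0 1 0 0 0"),
    (32, "Telson overlapped by previous somite", "telson not overlapped",
     "0 0 0 0 0 0 0 0 1 0 0 0"),
    (33, "Rostrum frontally with tuft of long setules", "no setular tuft",
     "0 0 0 0 0 0 0 0 0 0 1 0"),
    (34, "Abdominal somites except telson dorsally with paired cuticular "
     "longitudinal ridges", "such ridges absent",
     "0 0 0 0 0 0 0 0 0 0 1 0"),
    (35, "Abdominal somites except telson dorsally with pairs of long tube "
     "pores", "paired tube pores, if present, small",
     "0 0 0 0 0 0 0 0 0 0 1 0"),
    (36, "FR mid-laterally with accessory long tube pore",
     "lacking accessory tube pore",
     "0 0 0 0 0 0 0 0 0 0 1 0"),
    (37, "FR setae I and II displaced subapically", "arising mid-laterally",
     "0 0 0 0 0 0 0 0 0 0 1 0"),
    (38, "P5 male exopod: proximal lateral seta with STE", "seta lacking STE",
     "0 0 0 0 0 0 0 0 0 0 0 1"),
    (39, "P5 male exopod: subapical inner seta with STE", "seta lacking STE",
     "0 0 0 0 0 0 0 0 0 0 0 1"),
]

#: Bold cells of the source table: derived states regarded as convergent.
_CONVERGENCE_ANNOTATIONS = {
    (4, "L_macclintocki"),
    (5, "L_macclintocki"),
    (17, "L_spongiosus"),
}


def laophontodes_matrix() -> CharacterMatrix:
    """The packaged 39 x 12 polarity-coded character matrix."""
    characters = [
        CharacterDefinition(cid, desc, plesio, source_anchor="character table")
        for cid, desc, plesio, _ in _CHARACTERS
    ]
    cells = [
        [StateCode.parse(tok) for tok in row.split()]
        for _, _, _, row in _CHARACTERS
    ]
    return CharacterMatrix(TAXA, characters, cells, _CONVERGENCE_ANNOTATIONS)


def ripples_character() -> tuple[CharacterDefinition, list[StateCode]]:
    """The 'fine dorsal ripples' character, shipped separately for
    sensitivity analysis.

    Present in five species, confirmed absent in three, unknown elsewhere;
    treating it as a synapomorphy would demote the chirocer-antennule
    character suite to convergences, which is less parsimonious, so it is
    not part of the default matrix.
    """
    definition = CharacterDefinition(
        40,
        "Pedigerous and abdominal somites dorsally with fine ripples",
        "no dorsal ripples",
        source_anchor="discussion remarks",
    )
    row = [StateCode.parse(tok) for tok in "? 1 0 ? 0 ? 1 1 0 ? 1 1".split()]
    return definition, row


_REFERENCE_NEWICK = (
    "(L_whitsoni,L_macclintocki,L_sabinegeorgeae,(L_monsmaris,"
    "((L_mourois,L_typicus),(L_spongiosus,L_gertraudae,"
    "(L_georgei,(L_volkerlehmanskii,(L_sarsi,L_scottorum)))))));"
)

# Alternative reading of the published figure in which L. whitsoni is the
# first branch, the other two early taxa remaining unresolved.
_LADDER_NEWICK = (
    "(L_whitsoni,(L_macclintocki,L_sabinegeorgeae,(L_monsmaris,"
    "((L_mourois,L_typicus),(L_spongiosus,L_gertraudae,"
    "(L_georgei,(L_volkerlehmanskii,(L_sarsi,L_scottorum))))))));"
)


def reference_cladogram(variant: str = "polytomy") -> Cladogram:
    """The packaged reference cladogram.

    ``variant='polytomy'`` (default) keeps *L. whitsoni*, *L. macclintocki*
    and *L. sabinegeorgeae* in a root polytomy (their relationships are
    unresolved); ``variant='ladder'`` branches *L. whitsoni* first.
    """
    if variant == "polytomy":
        return parse_tree(_REFERENCE_NEWICK)
    if variant == "ladder":
        return parse_tree(_LADDER_NEWICK)
    raise ValueError(f"unknown variant {variant!r}")


# --- diagnostic key --------------------------------------------------------

_KEY_COUPLETS: dict[int, tuple[tuple[str, object], tuple[str, object]]] = {
    1: (("Body slender, cylindrical; cphth about 1/4th of total body length "
         "(incl. FR)", 2),
        ("Body compact, partially compressed dorsoventrally; cphth about "
         "1/3rd of total body length (incl. FR)", "L_scottorum")),
    2: (("Second antennular segment with flat posterior surface", 3),
        ("Second antennular segment with posterior surface produced into "
         "bump", 4)),
    3: (("Mxp of moderate size; P3 and P4exp-3 with 1 inner seta; telson not "
         "overlapped by preceding somite dorsally; male antennule "
         "subchirocer", "L_macclintocki"),
        ("Mxp extremely strengthened; P3 and P4exp-3 with 2 inner setae; "
         "telson overlapped by preceding somite; male antennule chirocer",
         "L_monsmaris")),
    4: (("Apical claw on P1enp-2 narrow and thin; male antennule subchirocer",
         5),
        ("Apical claw on P1enp-2 wide and thickened; male antennule chirocer "
         "or subchirocer", 6)),
    5: (("Pedigerous and abdominal somites dorsally with fine ripples; "
         "P2-P4exp-3 with 1:2:2 inner setae", "L_whitsoni"),
        ("No ripples on body somites, abdominal somites except telson "
         "dorsally with H-like cuticular structures; P2-P4 with 0:0:1 inner "
         "setae", "L_spongiosus")),
    6: (("P2 and P3exp-2 with 1 inner seta, P3 and P4exp-3 with 2 inner "
         "setae; rostrum with setulose tuft frontally; pedigerous and "
         "abdominal somites with fine ripples dorsally; abdominal somites "
         "except telson with paired cuticular ridges dorsally",
         "L_sabinegeorgeae"),
        ("These characters not combined", 7)),
    7: (("P4exp-3 inner apical seta short, flagelliform, bare", 8),
        ("P4exp-3 inner apical seta long, biplumose", 10)),
    8: (("P2 and P3exp-3 inner apical seta short, flagelliform, bare",
         "L_sarsi"),
        ("P2 and P3exp-3 inner apical seta long, biplumose", 9)),
    9: (("P2-P4exp-3 without inner setae; P4 endopod 1-segmented; inner "
         "margin of male P3enp-3 straight", "L_georgei"),
        ("P2-P4exp-3 with 1 inner seta; P4 endopod 2-segmented; inner margin "
         "of male P3enp-3 bulged out", "L_mourois")),
    10: (("P1exp-1 outer spine unipinnate, comb-shaped, with strong outer "
          "pinnae; anal operculum with row of fine spinules on apical "
          "margin", 11),
         ("P1exp-1 outer spine bipinnate, of normal shape; anal operculum "
          "with few strong spinules on apical margin", "L_volkerlehmanskii")),
    11: (("P2-P4-bearing somites with fine ripples dorsally; maxillipedal "
          "claw without accompanying minute seta; female P5 baseoendopodal "
          "inner seta fish-bone-like", "L_typicus"),
         ("P2-P4-bearing somites without ripples; maxillipedal claw with "
          "accompanying minute seta; female P5 baseoendopodal inner seta "
          "bipinnate, of normal shape", "L_gertraudae")),
}


def laophontodes_key() -> DichotomousKey:
    """The packaged 11-couplet diagnostic key to the 12 species."""
    couplets = {
        cid: (Lead(a_text, a_target), Lead(b_text, b_target))
        for cid, ((a_text, a_target), (b_text, b_target)) in _KEY_COUPLETS.items()
    }
    return DichotomousKey(couplets=couplets, start=1)
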