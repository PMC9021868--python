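"""Published per-cultivar requirement estimates for 20 apricot cultivars.

Mean chilling requirements (Dynamic-model chill portions, CP) and heat
requirements (growing degree hours, GDH) of 20 apricot cultivars grown at
Zaragoza (Spain), as determined by four break-estimation methods: the
forcing test, the correlation model, PLS regression, and the male-meiosis
biomarker.  These serve as worked-example inputs for the column-summary,
classification and Bland–Altman operations (the underlying multi-decade
weather record is not redistributable, so the per-cultivar summary values
are the natural interchange format).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["METHODS", "CULTIVARS", "chill_portions_table", "gdh_table"]

METHODS = ("forcing", "correlation", "pls", "biomarker")

# cultivar: ((CP mean, CP sd) per method, (GDH mean, GDH sd) per method),
# method order as in METHODS
_ROWS: dict[str, tuple] = {
    "Berdejo": ((47.2, 4.5), (57.0, 4.9), (54.2, 4.6), (61.9, 5.1),
                (5278, 706), (4917, 882), (3905, 948), (4170, 498)),
    "Canino": ((40.2, 6.1), (57.0, 4.9), (54.8, 4.7), (53.2, 6.2),
               (5026, 906), (4023, 784), (3634, 905), (4212, 765)),
    "Corbato": ((47.5, 1.5), (55.7, 4.8), (54.9, 4.5), (59.7, 4.6),
                (4814, 263), (4520, 864), (3640, 870), (3900, 440)),
    "Goldrich": ((42.0, 7.7), (56.4, 4.8), (53.6, 3.9), (58.3, 5.5),
                 (4749, 1146), (4086, 791), (4004, 976), (3712, 343)),
    "Gönci Magyar": ((60.2, 5.1), (69.1, 5.0), (74.8, 5.1), (66.8, 5.2),
                     (4288, 78), (4861, 887), (3448, 779), (4027, 513)),
    "Harcot": ((45.0, 2.5), (54.8, 4.9), (53.3, 4.1), (59.8, 5.2),
               (4767, 470), (4689, 873), (4209, 937), (3998, 402)),
    "Henderson": ((69.1, 5.2), (69.1, 5.0), (53.6, 3.9), (70.9, 10.4),
                  (2866, 666), (4441, 837), (4604, 1083), (4159, 968)),
    "Luizet": ((48.0, 4.0), (58.0, 4.9), (64.0, 4.5), (61.3, 4.8),
               (5076, 407), (4732, 858), (4004, 906), (4120, 437)),
    "Mitger": ((47.5, 1.5), (55.7, 4.8), (43.2, 3.9), (58.0, 5.4),
               (4777, 599), (4638, 860), (5326, 951), (4084, 467)),
    "Moniqui 1006": ((45.8, 3.5), (54.8, 4.9), (33.9, 4.6), (59.6, 5.3),
                     (4921, 399), (4821, 882), (4811, 921), (4045, 241)),
    "Moniqui 2113": ((49.8, 2.4), (55.7, 4.8), (55.0, 4.3), (61.7, 5.9),
                     (5144, 538), (4902, 884), (5305, 953), (4196, 542)),
    "Muñoz": ((46.5, 3.8), (57.0, 4.9), (58.6, 4.4), (59.1, 4.8),
              (5170, 799), (4650, 845), (3934, 881), (4185, 527)),
    "Pandora": ((45.8, 3.5), (57.0, 4.9), (53.6, 3.9), (60.7, 9.6),
                (4924, 993), (4141, 792), (3723, 926), (3863, 498)),
    "Paviot": ((47.2, 4.5), (57.0, 4.9), (54.3, 4.4), (61.6, 5.0),
               (5119, 551), (4781, 860), (3721, 886), (4135, 411)),
    "Pepito del Rubio": ((41.2, 4.1), (55.7, 4.8), (53.3, 4.3), (58.9, 5.1),
                         (5296, 646), (4638, 860), (3852, 894), (4019, 312)),
    "Stark Early Orange": ((60.4, 2.6), (70.7, 5.0), (76.7, 4.2), (71.4, 6.4),
                           (4152, 76), (4123, 758), (3607, 819), (4053, 1220)),
    "Stella": ((69.9, 6.7), (81.7, 5.3), (72.9, 4.5), (84.8, 7.5),
               (5936, 191), (4511, 638), (5468, 847), (3879, 746)),
    "Sun Glo": ((53.9, 3.5), (58.6, 4.9), (53.6, 3.9), (66.3, 7.0),
                (4915, 733), (4953, 944), (5054, 1174), (3789, 472)),
    "Tadeo": ((49.1, 2.4), (73.5, 5.0), (53.6, 3.9), (60.5, 5.3),
              (4742, 239), (3000, 514), (4604, 1083), (4126, 576)),
    "Veecot": ((48.9, 1.7), (58.0, 4.9), (54.6, 4.0), (54.5, 5.4),
               (4564, 700), (4091, 789), (4660, 1093), (4284, 898)),
}

CULTIVARS = tuple(_ROWS)


def chill_portions_table() -> pd.DataFrame:
    """Chilling requirements (CP): one row per cultivar, columns
    ``<method>`` (mean) and ``<method>_sd`` for each of the four methods."""
    data = {}
    for cultivar, row in _ROWS.items():
        rec = {}
        for m, (mean, sd) in zip(METHODS, row[:4]):
            rec[m] = mean
            rec[f"{m}_sd"] = sd
        data[cultivar] = rec
    return pd.DataFrame.from_dict(data, orient="index")


def gdh_table() -> pd.DataFrame:
    """Heat requirements (GDH), same layout as :func:`chill_portions_table`."""
    data = {}
    for cultivar, row in _ROWS.items():
        rec = {}
        for m, (mean, sd) in zip(METHODS, row[4:]):
            rec[m] = float(mean)
            rec[f"{m}_sd"] = float(sd)
        data[cultivar] = rec
    return pd.DataFrame.from_dict(data, orient="index")
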