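"""Published reference evaluation rows used as worked examples.

Each row of the feature-cohort table: (combination, r_pos, r_mom, rmse_pos
[deg], rmse_mom [Nm/kg], spm_pos fraction, spm_mom fraction, miscorrelation
score, RMSE score, SPM score, overall error score).  Names are canonical
('+'-joined, IEMG MAV RMS WL WAMP order).
"""

FEATURE_COHORT_ROWS = [
    ("IEMG+WL", 0.9006, 0.9742, 4.6781, 0.1094, 0.1000, 0.0000, 0.0626, 0.8670, 0.0500, 0.0027),
    ("IEMG+MAV+RMS+WAMP", 0.8948, 0.9718, 4.8151, 0.1158, 0.0600, 0.1200, 0.0667, 0.9046, 0.0900, 0.0054),
    ("MAV+RMS+WAMP", 0.8933, 0.9732, 4.8809, 0.1129, 0.0600, 0.2500, 0.0667, 0.8998, 0.1550, 0.0093),
    ("IEMG+RMS+WL", 0.9031, 0.9710, 4.6766, 0.1154, 0.0300, 0.3300, 0.0629, 0.8898, 0.1800, 0.0101),
    ("IEMG", 0.8955, 0.9780, 4.9175, 0.1090, 0.1500, 0.2200, 0.0633, 0.8883, 0.1850, 0.0104),
    ("IEMG+MAV+RMS+WL", 0.9095, 0.9747, 4.6147, 0.1096, 0.2000, 0.2500, 0.0579, 0.8617, 0.2250, 0.0112),
    ("IEMG+MAV+WL", 0.8962, 0.9758, 4.7377, 0.1083, 0.2100, 0.2000, 0.0640, 0.8684, 0.2050, 0.0114),
    ("IEMG+RMS+WAMP", 0.8940, 0.9727, 4.6181, 0.1160, 0.1400, 0.2500, 0.0667, 0.8865, 0.1950, 0.0115),
    ("WAMP", 0.8884, 0.9763, 4.9206, 0.1109, 0.1800, 0.2200, 0.0676, 0.8959, 0.2000, 0.0121),
    ("RMS", 0.8888, 0.9757, 5.0877, 0.1142, 0.1500, 0.2700, 0.0677, 0.9245, 0.2100, 0.0132),
    ("WL", 0.9006, 0.9814, 4.8743, 0.1020, 0.2400, 0.3200, 0.0590, 0.8574, 0.2800, 0.0142),
    ("MAV+WL+WAMP", 0.8860, 0.9734, 4.9387, 0.1154, 0.3200, 0.1300, 0.0703, 0.9149, 0.2250, 0.0145),
    ("RMS+WL+WAMP", 0.8987, 0.9706, 4.7733, 0.1145, 0.1900, 0.3100, 0.0653, 0.8956, 0.2500, 0.0146),
    ("IEMG+MAV+RMS", 0.9034, 0.9800, 4.7612, 0.1076, 0.0300, 0.6100, 0.0583, 0.8680, 0.3200, 0.0162),
    ("RMS+WL", 0.9023, 0.9782, 4.8670, 0.1062, 0.2300, 0.4000, 0.0597, 0.8728, 0.3150, 0.0164),
    ("MAV+RMS+WL", 0.8961, 0.9671, 4.8736, 0.1122, 0.3400, 0.2000, 0.0684, 0.8964, 0.2700, 0.0166),
    ("MAV", 0.8824, 0.9758, 5.1429, 0.1147, 0.1900, 0.3200, 0.0709, 0.9317, 0.2550, 0.0168),
    ("IEMG+MAV", 0.8885, 0.9745, 5.0225, 0.1142, 0.2000, 0.3500, 0.0685, 0.9183, 0.2750, 0.0173),
    ("IEMG+MAV+RMS+WL+WAMP", 0.9006, 0.9663, 4.5362, 0.1204, 0.1100, 0.4900, 0.0665, 0.8956, 0.3000, 0.0179),
    ("WL+WAMP", 0.8927, 0.9665, 4.7689, 0.1196, 0.0800, 0.5600, 0.0704, 0.9148, 0.3200, 0.0206),
    ("MAV+RMS+WL+WAMP", 0.8965, 0.9567, 4.8439, 0.1252, 0.1000, 0.5400, 0.0734, 0.9434, 0.3200, 0.0222),
    ("RMS+WAMP", 0.8776, 0.9730, 5.0264, 0.1168, 0.3900, 0.2600, 0.0747, 0.9287, 0.3250, 0.0225),
    ("MAV+RMS", 0.8765, 0.9766, 5.2271, 0.1132, 0.3000, 0.4000, 0.0734, 0.9340, 0.3500, 0.0240),
    ("IEMG+MAV+WL+WAMP", 0.8935, 0.9605, 4.6255, 0.1275, 0.1400, 0.5700, 0.0730, 0.9313, 0.3550, 0.0241),
    ("IEMG+RMS", 0.8952, 0.9744, 4.9570, 0.1120, 0.1800, 0.6800, 0.0652, 0.9036, 0.4300, 0.0253),
    ("IEMG+RMS+WL+WAMP", 0.8910, 0.9709, 4.8587, 0.1202, 0.6100, 0.2100, 0.0691, 0.9257, 0.4100, 0.0262),
    ("IEMG+WAMP", 0.8751, 0.9705, 5.0310, 0.1155, 0.5500, 0.2200, 0.0772, 0.9241, 0.3850, 0.0275),
    ("MAV+WAMP", 0.8827, 0.9766, 4.9713, 0.1144, 0.3600, 0.5200, 0.0703, 0.9142, 0.4400, 0.0283),
    ("IEMG+WL+WAMP", 0.8906, 0.9619, 4.8330, 0.1214, 0.6200, 0.2300, 0.0737, 0.9278, 0.4250, 0.0291),
    ("MAV+WL", 0.8924, 0.9796, 4.9329, 0.1064, 0.5900, 0.5800, 0.0640, 0.8798, 0.5850, 0.0329),
    ("IEMG+MAV+WAMP", 0.8768, 0.9611, 4.9993, 0.1304, 0.4800, 0.5900, 0.0811, 0.9782, 0.5350, 0.0424),
]

# Selected muscle-cohort rows: (combination, r_pos, r_mom, spm_pos, spm_mom,
# miscorrelation, RMSE score, SPM score, overall error score).
MUSCLE_COHORT_ROWS = {
    "MG+RF+VM": (0.9099, 0.9707, 0.0300, 0.0400, 0.0597, 0.8819, 0.0350, 0.0018),
    "GMax+VM": (0.9010, 0.9718, 0.0900, 0.2600, 0.0636, 0.9603, 0.1750, 0.0107),
}
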