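"""Frozen idealized toy geometries (synthetic; Angstrom).

Hard-coded CHON structures with 2-4 conformers each
(torsion-rotated where flexible, orientation-distinct
otherwise; pairwise RMSD >= 0.5 A on stored coordinates) and
deterministic chemically plausible ground-truth charges
summing exactly to the formal charge."""

TOY_MOLECULES = {
    'ethane': {
        'elements': ['C', 'C', 'H', 'H', 'H', 'H', 'H', 'H'],
        'atom_formal_charges': [0, 0, 0, 0, 0, 0, 0, 0],
        'formal_charge': 0,
        'bonds': [[0, 1, 1], [0, 2, 1], [0, 3, 1], [0, 4, 1], [1, 5, 1], [1, 6, 1], [1, 7, 1]],
        'true_charges': [-0.068262383421, -0.068262383421, 0.022754127807, 0.022754127807, 0.022754127807, 0.022754127807, 0.022754127807, 0.022754127806999987],
        'conformers': [[[-0.7554, -0.028, -0.0106], [0.7554, 0.028, 0.0106], [-1.1035, -1.059, 0.1031], [-1.1413, 0.3635, -0.9565], [-1.1737, 0.5687, 0.8055], [1.1413, -0.3635, 0.9565], [1.1737, -0.5687, -0.8055], [1.1035, 1.059, -0.1031]], [[0.028, -0.7554, -0.0106], [-0.028, 0.7554, 0.0106], [1.059, -1.1035, 0.1031], [-0.3635, -1.1413, -0.9565], [-0.5687, -1.1737, 0.8055], [0.3635, 1.1413, 0.9565], [0.5687, 1.1737, -0.8055], [-1.059, 1.1035, -0.1031]], [[-0.2164, -0.5671, 0.4507], [0.2164, 0.5671, -0.4507], [-1.007, -1.1555, -0.0243], [-0.5985, -0.1794, 1.3998], [0.6263, -1.2313, 0.6643], [0.5985, 0.1794, -1.3998], [-0.6263, 1.2313, -0.6643], [1.007, 1.1555, 0.0243]]],
    },
    'butane': {
        'elements': ['C', 'C', 'C', 'C', 'H', 'H', 'H', 'H', 'H', 'H', 'H', 'H', 'H', 'H'],
        'atom_formal_charges': [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        'formal_charge': 0,
        'bonds': [[0, 1, 1], [1, 2, 1], [2, 3, 1], [0, 4, 1], [0, 5, 1], [0, 6, 1], [1, 7, 1], [1, 8, 1], [2, 9, 1], [2, 10, 1], [3, 11, 1], [3, 12, 1], [3, 13, 1]],
        'true_charges': [-0.065392442881, -0.056434370418, -0.056434370418, -0.065392442881, 0.023035165389, 0.023035165389, 0.023035165389, 0.026360658565, 0.026360658565, 0.026360658565, 0.026360658565, 0.023035165389, 0.023035165389, 0.023035165393000014],
        'conformers': [[[1.9336, -0.0795, 0.0192], [0.5227, 0.1547, 0.5349], [-0.5227, -0.1547, -0.5349], [-1.9336, 0.0795, -0.0192], [2.1474, 0.5602, -0.8429], [2.6654, 0.1479, 0.8007], [2.0727, -1.1223, -0.2834], [0.3523, -0.4756, 1.4155], [0.4266, 1.1975, 0.8591], [-0.4266, -1.1974, -0.8591], [-0.3523, 0.4756, -1.4155], [-2.6654, -0.1479, -0.8007], [-2.1474, -0.5603, 0.8429], [-2.0727, 1.1223, 0.2834]], [[1.5062, 0.402, 0.2977], [0.0952, 0.6362, 0.8133], [-0.9501, 0.3269, -0.2565], [-0.8681, -1.1209, -0.7133], [1.72, 1.0418, -0.5645], [2.238, 0.6294, 1.0791], [1.6453, -0.6408, -0.005], [-0.0751, 0.0059, 1.6939], [-0.0008, 1.679, 1.1376], [-0.8049, 0.9855, -1.1207], [-1.9545, 0.5238, 0.1361], [-1.6247, -1.3203, -1.4786], [0.1148, -1.3421, -1.1415], [-1.0413, -1.8064, 0.1224]], [[1.4766, -0.263, 0.5188], [0.0657, -0.0289, 1.0345], [-0.9796, -0.3382, -0.0353], [-0.7944, 0.537, -1.2646], [1.6905, 0.3767, -0.3433], [2.2084, -0.0357, 1.3003], [1.6157, -1.3058, 0.2162], [-0.1046, -0.6591, 1.9151], [-0.0303, 1.0139, 1.3587], [-1.9858, -0.1804, 0.3703], [-0.9105, -1.3918, -0.3301], [-1.5527, 0.299, -2.0171], [-0.8901, 1.5972, -1.0095], [0.1913, 0.379, -1.7139]]],
    },
    'methanol': {
        'elements': ['C', 'O', 'H', 'H', 'H', 'H'],
        'atom_formal_charges': [0, 0, 0, 0, 0, 0],
        'formal_charge': 0,
        'bonds': [[0, 1, 1], [0, 2, 1], [0, 3, 1], [0, 4, 1], [1, 5, 1]],
        'true_charges': [0.031940683718, -0.399630243557, 0.052686631818, 0.052686631818, 0.052686631818, 0.20962966438500003],
        'conformers': [[[-0.3692, 0.0036, 0.0383], [0.9691, -0.2111, 0.4469], [-1.0388, -0.2663, 0.8583], [-0.51, 1.0579, -0.2122], [-0.5905, -0.6211, -0.8306], [1.5394, 0.0369, -0.3006]], [[-0.0036, -0.3692, 0.0383], [0.2111, 0.9691, 0.4469], [0.2663, -1.0388, 0.8583], [-1.0579, -0.51, -0.2122], [0.6211, -0.5905, -0.8306], [-0.0369, 1.5394, -0.3006]], [[-0.0662, -0.2994, 0.2092], [0.3576, 0.4004, -0.9462], [0.0662, -1.3713, 0.0439], [0.536, 0.0119, 1.0663], [-1.1221, -0.0895, 0.3966], [0.2284, 1.3479, -0.7698]]],
    },
    'ethanol': {
        'elements': ['C', 'C', 'O', 'H', 'H', 'H', 'H', 'H', 'H'],
        'atom_formal_charges': [0, 0, 0, 0, 0, 0, 0, 0, 0],
        'formal_charge': 0,
        'bonds': [[0, 1, 1], [1, 2, 1], [0, 3, 1], [0, 4, 1], [0, 5, 1], [1, 6, 1], [1, 7, 1], [2, 8, 1]],
        'true_charges': [-0.041838486155, 0.040220581749, -0.396663714781, 0.025373291592, 0.025373291592, 0.025373291592, 0.056069718921, 0.056069718921, 0.21002230656899998],
        'conformers': [[[0.8455, 0.2288, -0.2247], [-0.4336, -0.5391, 0.0365], [-1.5393, 0.3519, 0.0548], [1.7054, -0.446, -0.2584], [0.7828, 0.77, -1.1745], [1.0148, 0.9764, 0.5572], [-0.3883, -1.0623, 0.9965], [-0.6042, -1.2783, -0.7516], [-1.3831, 0.9985, 0.7641]], [[0.8674, 0.2524, -0.0494], [-0.4117, -0.5155, 0.2119], [-1.5174, 0.3755, 0.2302], [1.7273, -0.4224, -0.083], [0.8047, 0.7936, -0.9991], [1.0367, 1.0, 0.7326], [-0.3664, -1.0387, 1.1719], [-0.5823, -1.2547, -0.5762], [-1.5583, 0.8098, -0.6389]], [[-0.2288, 0.8455, -0.2247], [0.5391, -0.4336, 0.0365], [-0.3519, -1.5393, 0.0548], [0.446, 1.7054, -0.2584], [-0.77, 0.7828, -1.1745], [-0.9764, 1.0148, 0.5572], [1.0623, -0.3883, 0.9965], [1.2783, -0.6042, -0.7516], [-0.9985, -1.3831, 0.7641]]],
    },
    'acetamide': {
        'elements': ['C', 'C', 'O', 'N', 'H', 'H', 'H', 'H', 'H'],
        'atom_formal_charges': [0, 0, 0, 0, 0, 0, 0, 0, 0],
        'formal_charge': 0,
        'bonds': [[0, 1, 1], [1, 2, 2], [1, 3, 1], [0, 4, 1], [0, 5, 1], [0, 6, 1], [3, 7, 1], [3, 8, 1]],
        'true_charges': [0.014604156473, 0.213790179592, -0.275698462098, -0.369920587913, 0.033015348613, 0.033015348613, 0.033015348613, 0.159089334052, 0.15908933405499992],
        'conformers': [[[1.0896, -0.1965, 0.0201], [-0.2124, 0.5217, 0.2327], [-0.2875, 1.651, 0.7015], [-1.329, -0.1682, -0.13], [0.932, -1.2149, -0.3457], [1.6284, -0.2486, 0.97], [1.6851, 0.3523, -0.7143], [-2.2128, 0.3193, -0.057], [-1.2935, -1.0162, -0.6773]], [[0.1965, 1.0896, 0.0201], [-0.5217, -0.2124, 0.2327], [-1.651, -0.2875, 0.7015], [0.1682, -1.329, -0.13], [1.2149, 0.932, -0.3457], [0.2486, 1.6284, 0.97], [-0.3523, 1.6851, -0.7143], [-0.3193, -2.2128, -0.057], [1.0162, -1.2935, -0.6773]], [[0.1374, 0.7558, -0.7976], [0.4807, -0.1714, 0.3332], [1.596, -0.2324, 0.8363], [-0.538, -0.9592, 0.7758], [-0.8899, 0.607, -1.1418], [0.8146, 0.5652, -1.6344], [0.248, 1.7893, -0.459], [-0.3486, -1.5449, 1.5791], [-1.5003, -0.8093, 0.5085]]],
    },
    'methylamine': {
        'elements': ['C', 'N', 'H', 'H', 'H', 'H', 'H'],
        'atom_formal_charges': [0, 0, 0, 0, 0, 0, 0],
        'formal_charge': 0,
        'bonds': [[0, 1, 1], [0, 2, 1], [0, 3, 1], [0, 4, 1], [1, 5, 1], [1, 6, 1]],
        'true_charges': [-0.019502380004, -0.333269054757, 0.038858758728, 0.038858758728, 0.038858758728, 0.118097579288, 0.11809757928900007],
        'conformers': [[[-0.5718, 0.0445, -0.0343], [0.8554, 0.0323, -0.3009], [-0.9812, 1.0424, -0.2142], [-0.7717, -0.2348, 1.004], [-1.0851, -0.6619, -0.6926], [1.2295, -0.8943, -0.1008], [1.3249, 0.6718, 0.3388]], [[-0.0445, -0.5718, -0.0343], [-0.0323, 0.8554, -0.3009], [-1.0424, -0.9812, -0.2142], [0.2348, -0.7717, 1.004], [0.6619, -1.0851, -0.6926], [0.8943, 1.2295, -0.1008], [-0.6718, 1.3249, 0.3388]], [[-0.1306, -0.3967, 0.3946], [0.0538, 0.8339, -0.3535], [0.4054, -0.3441, 1.3463], [0.2458, -1.2523, -0.1732], [-1.1919, -0.5552, 0.6054], [-0.4251, 0.7602, -1.2502], [1.0426, 0.9542, -0.5694]]],
    },
    'acetate': {
        'elements': ['C', 'C', 'O', 'O', 'H', 'H', 'H'],
        'atom_formal_charges': [0, 0, 0, -1, 0, 0, 0],
        'formal_charge': -1,
        'bonds': [[0, 1, 1], [1, 2, 2], [1, 3, 1], [0, 4, 1], [0, 5, 1], [0, 6, 1]],
        'true_charges': [-0.024965368932, 0.038278598921, -0.550477028007, -0.550477028007, 0.029213608675, 0.029213608675, 0.029213608675000443],
        'conformers': [[[-0.6341, -0.0543, -0.0739], [0.8686, 0.0808, 0.1001], [1.3234, 1.2509, -0.0312], [1.4715, -0.9994, 0.3548], [-1.0988, 0.912, -0.2921], [-0.8515, -0.7372, -0.9006], [-1.079, -0.4529, 0.8428]], [[0.0543, -0.6341, -0.0739], [-0.0808, 0.8686, 0.1001], [-1.2509, 1.3234, -0.0312], [0.9994, 1.4715, 0.3548], [-0.912, -1.0988, -0.2921], [0.7372, -0.8515, -0.9006], [0.4529, -1.079, 0.8428]], [[-0.2445, -0.444, 0.392], [0.3391, 0.6103, -0.5325], [1.2499, 1.3244, -0.0288], [-0.1644, 0.6365, -1.6905], [0.2305, -0.4173, 1.3774], [-1.3173, -0.2714, 0.5203], [-0.0933, -1.4386, -0.038]]],
    },
    'methylammonium': {
        'elements': ['C', 'N', 'H', 'H', 'H', 'H', 'H', 'H'],
        'atom_formal_charges': [0, 1, 0, 0, 0, 0, 0, 0],
        'formal_charge': 1,
        'bonds': [[0, 1, 1], [0, 2, 1], [0, 3, 1], [0, 4, 1], [1, 5, 1], [1, 6, 1], [1, 7, 1]],
        'true_charges': [0.063389325437, -0.359999734417, 0.088429513219, 0.088429513219, 0.088429513219, 0.343773956441, 0.343773956441, 0.343773956441],
        'conformers': [[[-0.7527, -0.024, -0.0091], [0.7221, 0.023, 0.0087], [-1.0534, -1.0733, -0.0134], [-1.0921, 0.4854, -0.913], [-1.1138, 0.4842, 0.887], [1.1018, -0.4443, 0.8426], [1.1219, -0.4432, -0.8163], [1.0662, 0.9922, 0.0135]], [[0.024, -0.7527, -0.0091], [-0.023, 0.7221, 0.0087], [1.0733, -1.0534, -0.0134], [-0.4854, -1.0921, -0.913], [-0.4842, -1.1138, 0.887], [0.4443, 1.1018, 0.8426], [0.4432, 1.1219, -0.8163], [-0.9922, 1.0662, 0.0135]], [[-0.2117, -0.5649, 0.4508], [0.2031, 0.542, -0.4325], [-1.0766, -1.0501, -0.0055], [-0.4681, -0.1386, 1.4225], [0.6279, -1.2575, 0.5351], [0.4582, 0.1993, -1.3681], [-0.5518, 1.2305, -0.5503], [1.019, 1.0394, -0.052]]],
    },
    'benzene': {
        'elements': ['C', 'C', 'C', 'C', 'C', 'C', 'H', 'H', 'H', 'H', 'H', 'H'],
        'atom_formal_charges': [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        'formal_charge': 0,
        'bonds': [[0, 1, 4], [1, 2, 4], [2, 3, 4], [3, 4, 4], [4, 5, 4], [5, 0, 4], [0, 6, 1], [1, 7, 1], [2, 8, 1], [3, 9, 1], [4, 10, 1], [5, 11, 1]],
        'true_charges': [-0.062268570782, -0.062268570782, -0.062268570782, -0.062268570782, -0.062268570782, -0.062268570782, 0.062268570782, 0.062268570782, 0.062268570782, 0.062268570782, 0.062268570782, 0.062268570782000016],
        'conformers': [[[-1.0732, -0.8908, -0.0182], [-1.3081, 0.4841, -0.0129], [-0.2349, 1.3749, 0.0053], [1.0732, 0.8908, 0.0182], [1.3081, -0.4841, 0.0129], [0.2349, -1.3749, -0.0053], [-1.9093, -1.5849, -0.0323], [-2.3272, 0.8612, -0.0229], [-0.4179, 2.4461, 0.0094], [1.9093, 1.5849, 0.0323], [2.3272, -0.8612, 0.0229], [0.4179, -2.4461, -0.0094]], [[0.8908, -1.0732, -0.0182], [-0.4841, -1.3081, -0.0129], [-1.3749, -0.2349, 0.0053], [-0.8908, 1.0732, 0.0182], [0.4841, 1.3081, 0.0129], [1.3749, 0.2349, -0.0053], [1.5849, -1.9093, -0.0323], [-0.8612, -2.3272, -0.0229], [-2.4461, -0.4179, 0.0094], [-1.5849, 1.9093, 0.0323], [0.8612, 2.3272, 0.0229], [2.4461, 0.4179, -0.0094]], [[-0.9475, -1.0164, 0.1208], [0.0281, -0.8521, 1.1039], [0.9757, 0.1643, 0.9832], [0.9475, 1.0164, -0.1208], [-0.0281, 0.8521, -1.1039], [-0.9757, -0.1643, -0.9832], [-1.6858, -1.8084, 0.2148], [0.0501, -1.516, 1.964], [1.7358, 0.2923, 1.7491], [1.6858, 1.8084, -0.2148], [-0.0501, 1.516, -1.964], [-1.7358, -0.2923, -1.7491]]],
    },
}
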