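"""Precomputed finite-sample null calibration for the local-similarity
statistic (generated by scripts/build_null_table.py; do not edit).

LN_TAIL[i, j] = log P(X >= X_GRID[j]) under the rank-score permutation
null at series length N_GRID[i], where X is the local-similarity score
standardized as LS*sqrt(n)/s2_n.  LN_TAIL_ASYM is the n->infinity
(Brownian-range) limit used for extrapolation beyond the grid."""
import numpy as np

N_GRID = np.array([15, 20, 25, 30, 40, 50, 65, 80, 100, 120, 150, 200, 300, 500, 750, 1000])

X_GRID = np.round(np.arange(0.05, 7.0 + 1e-9, 0.05), 2)

LN_TAIL = np.array([
    [
        0.000000, 0.000000, 0.000000, 0.000000, 0.000000, -0.000005,
        -0.000032, -0.000303, -0.001005, -0.003387, -0.007920, -0.015888,
        -0.030608, -0.050884, -0.076107, -0.109403, -0.145934, -0.202967,
        -0.260535, -0.324067, -0.394717, -0.468569, -0.549681, -0.633330,
        -0.722827, -0.815353, -0.912438, -1.013857, -1.117260, -1.222724,
        -1.335385, -1.449089, -1.567260, -1.687535, -1.814293, -1.941100,
        -2.071910, -2.208922, -2.350128, -2.496777, -2.645413, -2.799426,
        -2.960404, -3.123929, -3.291285, -3.471352, -3.648544, -3.839981,
        -4.041790, -4.249596, -4.463410, -4.682159, -4.918238, -5.162040,
        -5.415301, -5.684568, -5.957643, -6.245583, -6.552882, -6.888934,
        -7.241830, -7.596910, -7.963308, -8.343240, -8.517889, -8.694880,
        -8.874217, -9.055902, -9.239938, -9.426329, -9.615078, -9.806188,
        -9.999661, -10.195500, -10.393707, -10.594286, -10.797239, -11.002569,
        -11.210277, -11.420366, -11.632838, -11.847696, -12.064941, -12.284577,
        -12.506604, -12.731025, -12.957841, -13.187056, -13.418669, -13.652684,
        -13.889102, -14.127924, -14.369153, -14.612790, -14.858836, -15.107293,
        -15.358163, -15.611447, -15.867146, -16.125263, -16.385797, -16.648751,
        -16.914126, -17.181924, -17.452144, -17.724789, -17.999861, -18.277359,
        -18.557285, -18.839641, -19.124426, -19.411644, -19.701293, -19.993377,
        -20.287894, -20.584847, -20.884237, -21.186064, -21.490329, -21.797033,
        -22.106177, -22.417763, -22.731789, -23.048259, -23.367172, -23.688529,
        -24.012331, -24.338578, -24.667272, -24.998414, -25.332003, -25.668041,
        -26.006528, -26.347464, -26.690852, -27.036691, -27.384982, -27.735725,
        -28.088921, -28.444572,
    ],
    [
        0.000000, 0.000000, 0.000000, 0.000000, 0.000000, 0.000000,
        -0.000009, -0.000089, -0.000513, -0.001645, -0.005012, -0.011185,
        -0.022389, -0.038871, -0.061845, -0.091129, -0.131399, -0.176828,
        -0.229676, -0.289661, -0.355489, -0.427343, -0.504477, -0.587266,
        -0.674355, -0.765243, -0.860036, -0.959425, -1.061464, -1.166151,
        -1.273598, -1.384895, -1.500633, -1.620423, -1.742215, -1.865111,
        -1.990508, -2.122499, -2.257956, -2.397193, -2.540094, -2.689557,
        -2.840919, -2.999299, -3.158675, -3.322072, -3.493181, -3.674543,
        -3.857109, -4.042986, -4.237545, -4.430629, -4.639244, -4.837102,
        -5.046159, -5.270119, -5.493846, -5.739928, -5.996678, -6.251272,
        -6.505629, -6.765388, -7.065579, -7.320245, -7.639643, -7.957577,
        -8.262551, -8.444236, -8.628272, -8.814664, -9.003413, -9.194522,
        -9.387995, -9.583834, -9.782041, -9.982620, -10.185573, -10.390903,
        -10.598611, -10.808700, -11.021172, -11.236030, -11.453276, -11.672911,
        -11.894938, -12.119359, -12.346175, -12.575390, -12.807003, -13.041018,
        -13.277436, -13.516258, -13.757487, -14.001124, -14.247170, -14.495627,
        -14.746497, -14.999781, -15.255480, -15.513597, -15.774131, -16.037085,
        -16.302460, -16.570258, -16.840478, -17.113124, -17.388195, -17.665693,
        -17.945619, -18.227975, -18.512761, -18.799978, -19.089628, -19.381711,
        -19.676228, -19.973182, -20.272571, -20.574398, -20.878663, -21.185367,
        -21.494512, -21.806097, -22.120124, -22.436593, -22.755506, -23.076863,
        -23.400665, -23.726912, -24.055607, -24.386748, -24.720337, -25.056375,
        -25.394862, -25.735799, -26.079186, -26.425025, -26.773316, -27.124059,
        -27.477256, -27.832906,
    ],
    [
        0.000000, 0.000000, 0.000000, 0.000000, 0.000000, 0.000000,
        -0.000003, -0.000069, -0.000316, -0.001243, -0.003704, -0.008658,
        -0.017872, -0.032521, -0.052786, -0.080930, -0.116995, -0.160100,
        -0.210533, -0.267579, -0.331312, -0.401684, -0.477193, -0.557835,
        -0.642351, -0.731223, -0.824863, -0.922618, -1.023940, -1.128476,
        -1.235367, -1.346128, -1.459162, -1.575713, -1.693695, -1.816173,
        -1.942222, -2.071997, -2.203690, -2.338295, -2.479489, -2.622501,
        -2.769856, -2.915702, -3.071728, -3.232797, -3.396120, -3.558940,
        -3.728078, -3.903063, -4.086019, -4.270485, -4.450905, -4.645263,
        -4.852606, -5.066254, -5.282050, -5.506326, -5.723883, -5.966577,
        -6.199227, -6.456680, -6.706448, -6.974964, -7.267291, -7.590952,
        -7.904714, -8.209708, -8.487634, -8.674026, -8.862774, -9.053884,
        -9.247357, -9.443196, -9.641403, -9.841982, -10.044935, -10.250265,
        -10.457973, -10.668062, -10.880534, -11.095392, -11.312638, -11.532273,
        -11.754300, -11.978721, -12.205537, -12.434752, -12.666365, -12.900380,
        -13.136798, -13.375620, -13.616849, -13.860486, -14.106532, -14.354989,
        -14.605859, -14.859143, -15.114842, -15.372959, -15.633493, -15.896447,
        -16.161822, -16.429620, -16.699840, -16.972486, -17.247557, -17.525055,
        -17.804981, -18.087337, -18.372123, -18.659340, -18.948990, -19.241073,
        -19.535590, -19.832543, -20.131933, -20.433760, -20.738025, -21.044729,
        -21.353874, -21.665459, -21.979486, -22.295955, -22.614868, -22.936225,
        -23.260027, -23.586274, -23.914969, -24.246110, -24.579699, -24.915737,
        -25.254224, -25.595161, -25.938548, -26.284387, -26.632678, -26.983421,
        -27.336618, -27.692268,
    ],
    [
        0.000000, 0.000000, 0.000000, 0.000000, 0.000000, 0.000000,
        -0.000003, -0.000025, -0.000188, -0.000810, -0.002661, -0.006704,
        -0.014760, -0.027661, -0.046635, -0.073053, -0.106502, -0.147400,
        -0.194955, -0.250000, -0.311831, -0.379286, -0.452601, -0.531804,
        -0.615694, -0.704920, -0.796873, -0.892877, -0.991917, -1.095797,
        -1.203107, -1.314163, -1.426084, -1.541298, -1.658717, -1.778182,
        -1.902796, -2.029562, -2.158675, -2.290321, -2.426608, -2.565327,
        -2.708240, -2.853920, -3.003180, -3.157193, -3.317068, -3.479884,
        -3.645935, -3.818715, -3.995187, -4.171701, -4.350063, -4.535831,
        -4.724630, -4.917965, -5.126888, -5.335812, -5.538861, -5.755918,
        -5.978351, -6.221633, -6.455407, -6.687015, -6.928979, -7.199445,
        -7.469874, -7.770505, -8.034767, -8.274247, -8.462996, -8.654105,
        -8.847578, -9.043417, -9.241625, -9.442204, -9.645157, -9.850486,
        -10.058194, -10.268283, -10.480756, -10.695613, -10.912859, -11.132494,
        -11.354521, -11.578942, -11.805759, -12.034973, -12.266587, -12.500601,
        -12.737019, -12.975842, -13.217070, -13.460707, -13.706753, -13.955211,
        -14.206080, -14.459364, -14.715064, -14.973180, -15.233715, -15.496669,
        -15.762044, -16.029841, -16.300062, -16.572707, -16.847778, -17.125276,
        -17.405203, -17.687558, -17.972344, -18.259561, -18.549211, -18.841294,
        -19.135812, -19.432765, -19.732154, -20.033981, -20.338246, -20.644951,
        -20.954095, -21.265680, -21.579707, -21.896176, -22.215089, -22.536446,
        -22.860248, -23.186496, -23.515190, -23.846331, -24.179920, -24.515958,
        -24.854445, -25.195382, -25.538770, -25.884608, -26.232899, -26.583643,
        -26.936839, -27.292489,
    ],
    [
        0.000000, 0.000000, 0.000000, 0.000000, 0.000000, 0.000000,
        -0.000005, -0.000016, -0.000088, -0.000475, -0.001717, -0.004730,
        -0.010976, -0.021567, -0.037749, -0.060718, -0.090877, -0.128447,
        -0.173478, -0.225331, -0.284361, -0.349941, -0.420810, -0.497059,
        -0.578783, -0.663930, -0.754580, -0.848455, -0.944865, -1.045850,
        -1.150331, -1.257711, -1.367512, -1.480535, -1.596532, -1.715293,
        -1.838505, -1.963865, -2.091668, -2.222029, -2.354658, -2.492342,
        -2.632674, -2.776003, -2.920272, -3.072160, -3.226253, -3.381807,
        -3.543084, -3.703628, -3.868341, -4.038267, -4.210160, -4.391592,
        -4.572026, -4.764987, -4.954444, -5.140289, -5.345409, -5.555535,
        -5.770243, -5.985880, -6.201198, -6.405769, -6.630124, -6.864696,
        -7.109871, -7.347812, -7.596910, -7.819058, -8.088663, -8.390561,
        -8.584033, -8.779872, -8.978080, -9.178659, -9.381612, -9.586941,
        -9.794649, -10.004738, -10.217211, -10.432069, -10.649314, -10.868950,
        -11.090977, -11.315398, -11.542214, -11.771428, -12.003042, -12.237057,
        -12.473474, -12.712297, -12.953526, -13.197162, -13.443208, -13.691666,
        -13.942536, -14.195820, -14.451519, -14.709635, -14.970170, -15.233124,
        -15.498499, -15.766296, -16.036517, -16.309162, -16.584233, -16.861731,
        -17.141658, -17.424013, -17.708799, -17.996016, -18.285666, -18.577749,
        -18.872267, -19.169220, -19.468610, -19.770436, -20.074702, -20.381406,
        -20.690550, -21.002135, -21.316162, -21.632632, -21.951545, -22.272902,
        -22.596703, -22.922951, -23.251645, -23.582786, -23.916376, -24.252413,
        -24.590900, -24.931837, -25.275225, -25.621064, -25.969354, -26.320098,
        -26.673294, -27.028944,
    ],
    [
        0.000000, 0.000000, 0.000000, 0.000000, 0.000000, 0.000000,
        0.000000, -0.000004, -0.000045, -0.000301, -0.001168, -0.003481,
        -0.008565, -0.017672, -0.032076, -0.053028, -0.080971, -0.116202,
        -0.158787, -0.208246, -0.264631, -0.327981, -0.396884, -0.471632,
        -0.551366, -0.635307, -0.724004, -0.817389, -0.914697, -1.015457,
        -1.118789, -1.224210, -1.333801, -1.446669, -1.562774, -1.680639,
        -1.800592, -1.922985, -2.049650, -2.178184, -2.310083, -2.444022,
        -2.582458, -2.721242, -2.862671, -3.006530, -3.153392, -3.308609,
        -3.465512, -3.623804, -3.784862, -3.947754, -4.117756, -4.285190,
        -4.457354, -4.633158, -4.817497, -4.999992, -5.184453, -5.376928,
        -5.574598, -5.781852, -5.995071, -6.201198, -6.424712, -6.665594,
        -6.889915, -7.095290, -7.338538, -7.571344, -7.857086, -8.149084,
        -8.364472, -8.560311, -8.758519, -8.959098, -9.162051, -9.367380,
        -9.575088, -9.785177, -9.997650, -10.212507, -10.429753, -10.649388,
        -10.871415, -11.095836, -11.322653, -11.551867, -11.783481, -12.017495,
        -12.253913, -12.492736, -12.733964, -12.977601, -13.223647, -13.472105,
        -13.722974, -13.976258, -14.231958, -14.490074, -14.750609, -15.013563,
        -15.278938, -15.546735, -15.816956, -16.089601, -16.364672, -16.642170,
        -16.922096, -17.204452, -17.489238, -17.776455, -18.066105, -18.358188,
        -18.652706, -18.949659, -19.249048, -19.550875, -19.855140, -20.161845,
        -20.470989, -20.782574, -21.096601, -21.413070, -21.731983, -22.053340,
        -22.377142, -22.703390, -23.032084, -23.363225, -23.696814, -24.032852,
        -24.371339, -24.712276, -25.055664, -25.401502, -25.749793, -26.100536,
        -26.453733, -26.809383,
    ],
    [
        0.000000, 0.000000, 0.000000, 0.000000, 0.000000, 0.000000,
        0.000000, -0.000002, -0.000035, -0.000186, -0.000787, -0.002652,
        -0.006526, -0.014106, -0.026497, -0.045088, -0.070613, -0.103350,
        -0.143683, -0.190874, -0.245610, -0.306046, -0.372974, -0.445669,
        -0.524266, -0.607417, -0.694484, -0.785302, -0.880436, -0.978621,
        -1.080240, -1.184700, -1.293230, -1.404381, -1.518469, -1.634745,
        -1.754117, -1.876768, -2.001851, -2.129145, -2.259708, -2.391886,
        -2.527105, -2.664488, -2.803790, -2.946714, -3.092596, -3.240789,
        -3.392991, -3.548596, -3.708633, -3.873187, -4.035830, -4.204048,
        -4.375011, -4.541914, -4.723729, -4.906546, -5.095213, -5.284414,
        -5.476010, -5.677530, -5.873504, -6.073977, -6.251272, -6.474675,
        -6.685412, -6.897805, -7.089277, -7.299317, -7.552112, -7.801795,
        -8.025550, -8.298058, -8.496265, -8.696844, -8.899797, -9.105127,
        -9.312835, -9.522924, -9.735396, -9.950254, -10.167500, -10.387135,
        -10.609162, -10.833583, -11.060399, -11.289614, -11.521227, -11.755242,
        -11.991660, -12.230482, -12.471711, -12.715348, -12.961394, -13.209851,
        -13.460721, -13.714005, -13.969704, -14.227821, -14.488355, -14.751309,
        -15.016684, -15.284482, -15.554702, -15.827348, -16.102419, -16.379917,
        -16.659843, -16.942199, -17.226985, -17.514202, -17.803852, -18.095935,
        -18.390452, -18.687405, -18.986795, -19.288622, -19.592887, -19.899591,
        -20.208736, -20.520321, -20.834348, -21.150817, -21.469730, -21.791087,
        -22.114889, -22.441136, -22.769831, -23.100972, -23.434561, -23.770599,
        -24.109086, -24.450023, -24.793410, -25.139249, -25.487540, -25.838283,
        -26.191480, -26.547130,
    ],
    [
        0.000000, 0.000000, 0.000000, 0.000000, 0.000000, 0.000000,
        0.000000, -0.000004, -0.000018, -0.000108, -0.000540, -0.001956,
        -0.005311, -0.011937, -0.023141, -0.040121, -0.064012, -0.094950,
        -0.133052, -0.178384, -0.230624, -0.289959, -0.355035, -0.426454,
        -0.503416, -0.585111, -0.671196, -0.761188, -0.855494, -0.953235,
        -1.054519, -1.159057, -1.265770, -1.375916, -1.488757, -1.603699,
        -1.721308, -1.843864, -1.967149, -2.093784, -2.223857, -2.354721,
        -2.489746, -2.625922, -2.763589, -2.905453, -3.051351, -3.200741,
        -3.352836, -3.503961, -3.663290, -3.823783, -3.989444, -4.147113,
        -4.314443, -4.491842, -4.668643, -4.841779, -5.016603, -5.199559,
        -5.374335, -5.555276, -5.744292, -5.942674, -6.149289, -6.344717,
        -6.556394, -6.774974, -6.980326, -7.195437, -7.421920, -7.660652,
        -7.946214, -8.166536, -8.408339, -8.608918, -8.811871, -9.017200,
        -9.224908, -9.434997, -9.647470, -9.862327, -10.079573, -10.299208,
        -10.521235, -10.745656, -10.972473, -11.201687, -11.433301, -11.667315,
        -11.903733, -12.142556, -12.383784, -12.627421, -12.873467, -13.121925,
        -13.372794, -13.626078, -13.881778, -14.139894, -14.400429, -14.663383,
        -14.928758, -15.196555, -15.466776, -15.739421, -16.014492, -16.291990,
        -16.571917, -16.854272, -17.139058, -17.426275, -17.715925, -18.008008,
        -18.302526, -18.599479, -18.898868, -19.200695, -19.504960, -19.811665,
        -20.120809, -20.432394, -20.746421, -21.062891, -21.381803, -21.703160,
        -22.026962, -22.353210, -22.681904, -23.013045, -23.346634, -23.682672,
        -24.021159, -24.362096, -24.705484, -25.051322, -25.399613, -25.750357,
        -26.103553, -26.459203,
    ],
    [
        0.000000, 0.000000, 0.000000, 0.000000, 0.000000, 0.000000,
        0.000000, 0.000000, -0.000008, -0.000092, -0.000436, -0.001485,
        -0.004285, -0.009900, -0.019794, -0.035318, -0.056886, -0.085350,
        -0.121361, -0.164964, -0.215597, -0.272910, -0.336961, -0.406345,
        -0.481351, -0.561596, -0.646229, -0.735393, -0.828532, -0.925836,
        -1.026139, -1.128887, -1.235670, -1.344795, -1.456781, -1.570972,
        -1.686384, -1.807858, -1.929877, -2.056014, -2.185327, -2.317019,
        -2.450134, -2.584603, -2.721880, -2.862653, -3.006369, -3.151030,
        -3.299652, -3.449013, -3.601052, -3.753610, -3.909277, -4.069379,
        -4.237476, -4.412403, -4.573962, -4.748579, -4.931177, -5.102586,
        -5.282641, -5.463428, -5.647591, -5.830707, -6.021924, -6.217613,
        -6.421632, -6.615832, -6.841968, -7.051626, -7.255895, -7.457668,
        -7.677784, -7.899308, -8.152550, -8.403865, -8.606817, -8.812147,
        -9.019855, -9.229944, -9.442416, -9.657274, -9.874520, -10.094155,
        -10.316182, -10.540603, -10.767420, -10.996634, -11.228247, -11.462262,
        -11.698680, -11.937502, -12.178731, -12.422368, -12.668414, -12.916871,
        -13.167741, -13.421025, -13.676724, -13.934841, -14.195375, -14.458329,
        -14.723705, -14.991502, -15.261722, -15.534368, -15.809439, -16.086937,
        -16.366863, -16.649219, -16.934005, -17.221222, -17.510872, -17.802955,
        -18.097472, -18.394426, -18.693815, -18.995642, -19.299907, -19.606611,
        -19.915756, -20.227341, -20.541368, -20.857837, -21.176750, -21.498107,
        -21.821909, -22.148157, -22.476851, -22.807992, -23.141581, -23.477619,
        -23.816106, -24.157043, -24.500430, -24.846269, -25.194560, -25.545303,
        -25.898500, -26.254150,
    ],
    [
        0.000000, 0.000000, 0.000000, 0.000000, 0.000000, 0.000000,
        0.000000, 0.000000, -0.000009, -0.000049, -0.000313, -0.001215,
        -0.003650, -0.008709, -0.017772, -0.031883, -0.052318, -0.079962,
        -0.114919, -0.156988, -0.206419, -0.261791, -0.324639, -0.393306,
        -0.467458, -0.546543, -0.630015, -0.717944, -0.810421, -0.905482,
        -1.004060, -1.105909, -1.211578, -1.320675, -1.431484, -1.545126,
        -1.661721, -1.780665, -1.902582, -2.026341, -2.155269, -2.285001,
        -2.414344, -2.545829, -2.679594, -2.817636, -2.959593, -3.106262,
        -3.252769, -3.400937, -3.554838, -3.708796, -3.867050, -4.029569,
        -4.189425, -4.362146, -4.535364, -4.700470, -4.877898, -5.050989,
        -5.232342, -5.418002, -5.605930, -5.815496, -6.004347, -6.183109,
        -6.377715, -6.569142, -6.782886, -6.993313, -7.206161, -7.405336,
        -7.645900, -7.824046, -8.044069, -8.298058, -8.512206, -8.717535,
        -8.925243, -9.135332, -9.347804, -9.562662, -9.779908, -9.999543,
        -10.221570, -10.445991, -10.672808, -10.902022, -11.133635, -11.367650,
        -11.604068, -11.842890, -12.084119, -12.327756, -12.573802, -12.822259,
        -13.073129, -13.326413, -13.582113, -13.840229, -14.100763, -14.363718,
        -14.629093, -14.896890, -15.167111, -15.439756, -15.714827, -15.992325,
        -16.272251, -16.554607, -16.839393, -17.126610, -17.416260, -17.708343,
        -18.002861, -18.299814, -18.599203, -18.901030, -19.205295, -19.512000,
        -19.821144, -20.132729, -20.446756, -20.763225, -21.082138, -21.403495,
        -21.727297, -22.053545, -22.382239, -22.713380, -23.046969, -23.383007,
        -23.721494, -24.062431, -24.405818, -24.751657, -25.099948, -25.450691,
        -25.803888, -26.159538,
    ],
    [
        0.000000, 0.000000, 0.000000, 0.000000, 0.000000, 0.000000,
        0.000000, 0.000000, -0.000002, -0.000033, -0.000262, -0.000947,
        -0.002817, -0.007115, -0.015198, -0.028319, -0.047618, -0.073243,
        -0.106378, -0.146482, -0.194084, -0.248470, -0.308842, -0.376426,
        -0.448772, -0.526709, -0.609563, -0.696693, -0.787894, -0.882332,
        -0.980376, -1.082591, -1.186641, -1.293879, -1.404221, -1.516912,
        -1.633108, -1.751693, -1.871246, -1.993386, -2.118515, -2.246835,
        -2.377345, -2.509343, -2.645568, -2.783663, -2.923443, -3.066441,
        -3.211817, -3.361064, -3.513806, -3.666140, -3.820432, -3.977896,
        -4.142695, -4.308404, -4.471660, -4.637521, -4.811375, -4.985943,
        -5.158845, -5.333599, -5.517718, -5.692348, -5.889510, -6.059743,
        -6.274712, -6.460935, -6.644110, -6.873354, -7.090077, -7.295872,
        -7.514725, -7.680667, -7.893039, -8.093618, -8.296571, -8.501900,
        -8.709608, -8.919697, -9.132170, -9.347028, -9.564273, -9.783908,
        -10.005936, -10.230356, -10.457173, -10.686387, -10.918001, -11.152016,
        -11.388433, -11.627256, -11.868484, -12.112121, -12.358167, -12.606625,
        -12.857495, -13.110778, -13.366478, -13.624594, -13.885129, -14.148083,
        -14.413458, -14.681255, -14.951476, -15.224121, -15.499192, -15.776690,
        -16.056617, -16.338972, -16.623758, -16.910975, -17.200625, -17.492708,
        -17.787226, -18.084179, -18.383569, -18.685395, -18.989660, -19.296365,
        -19.605509, -19.917094, -20.231121, -20.547591, -20.866503, -21.187860,
        -21.511662, -21.837910, -22.166604, -22.497745, -22.831334, -23.167372,
        -23.505859, -23.846796, -24.190184, -24.536023, -24.884313, -25.235057,
        -25.588253, -25.943903,
    ],
    [
        0.000000, 0.000000, 0.000000, 0.000000, 0.000000, 0.000000,
        0.000000, 0.000000, 0.000000, -0.000023, -0.000140, -0.000734,
        -0.002361, -0.006073, -0.013154, -0.024742, -0.042273, -0.066355,
        -0.096856, -0.135587, -0.181374, -0.233533, -0.292748, -0.358004,
        -0.428330, -0.504540, -0.585950, -0.672061, -0.762061, -0.854298,
        -0.952752, -1.052626, -1.155490, -1.262067, -1.373062, -1.485820,
        -1.602272, -1.720230, -1.840572, -1.963058, -2.088523, -2.214559,
        -2.343251, -2.475769, -2.611831, -2.745570, -2.883505, -3.024475,
        -3.171118, -3.320770, -3.474952, -3.627408, -3.776618, -3.939480,
        -4.095045, -4.259337, -4.420490, -4.591760, -4.760850, -4.941576,
        -5.107146, -5.291011, -5.483844, -5.661202, -5.847653, -6.028820,
        -6.220459, -6.399934, -6.608886, -6.789972, -6.989327, -7.188793,
        -7.432567, -7.655711, -7.884150, -8.084729, -8.287682, -8.493011,
        -8.700719, -8.910808, -9.123281, -9.338139, -9.555384, -9.775020,
        -9.997047, -10.221467, -10.448284, -10.677498, -10.909112, -11.143127,
        -11.379544, -11.618367, -11.859596, -12.103232, -12.349278, -12.597736,
        -12.848606, -13.101890, -13.357589, -13.615705, -13.876240, -14.139194,
        -14.404569, -14.672366, -14.942587, -15.215232, -15.490303, -15.767801,
        -16.047728, -16.330083, -16.614869, -16.902086, -17.191736, -17.483819,
        -17.778337, -18.075290, -18.374680, -18.676506, -18.980772, -19.287476,
        -19.596620, -19.908205, -20.222232, -20.538702, -20.857614, -21.178971,
        -21.502773, -21.829021, -22.157715, -22.488856, -22.822445, -23.158483,
        -23.496970, -23.837907, -24.181295, -24.527134, -24.875424, -25.226168,
        -25.579364, -25.935014,
    ],
    [
        0.000000, 0.000000, 0.000000, 0.000000, 0.000000, 0.000000,
        0.000000, 0.000000, -0.000003, -0.000022, -0.000082, -0.000417,
        -0.001519, -0.004398, -0.009889, -0.019837, -0.035080, -0.056805,
        -0.085327, -0.121351, -0.164391, -0.214615, -0.271398, -0.335361,
        -0.404878, -0.480326, -0.559336, -0.643237, -0.731310, -0.822823,
        -0.919893, -1.019935, -1.123458, -1.229735, -1.338749, -1.449824,
        -1.564058, -1.680406, -1.798240, -1.920229, -2.045233, -2.171148,
        -2.299889, -2.431214, -2.566855, -2.699289, -2.839042, -2.980877,
        -3.124437, -3.269424, -3.420533, -3.572579, -3.722712, -3.881171,
        -4.042606, -4.205723, -4.373001, -4.549735, -4.714427, -4.880485,
        -5.056417, -5.215816, -5.386784, -5.558817, -5.738892, -5.918834,
        -6.102769, -6.296180, -6.483577, -6.664809, -6.889588, -7.088079,
        -7.320749, -7.539494, -7.783224, -7.986565, -8.189518, -8.394847,
        -8.602555, -8.812644, -9.025117, -9.239975, -9.457220, -9.676855,
        -9.898883, -10.123303, -10.350120, -10.579334, -10.810948, -11.044963,
        -11.281380, -11.520203, -11.761431, -12.005068, -12.251114, -12.499572,
        -12.750442, -13.003725, -13.259425, -13.517541, -13.778076, -14.041030,
        -14.306405, -14.574202, -14.844423, -15.117068, -15.392139, -15.669637,
        -15.949564, -16.231919, -16.516705, -16.803922, -17.093572, -17.385655,
        -17.680173, -17.977126, -18.276516, -18.578342, -18.882607, -19.189312,
        -19.498456, -19.810041, -20.124068, -20.440538, -20.759450, -21.080807,
        -21.404609, -21.730857, -22.059551, -22.390692, -22.724281, -23.060319,
        -23.398806, -23.739743, -24.083131, -24.428970, -24.777260, -25.128004,
        -25.481200, -25.836850,
    ],
    [
        0.000000, 0.000000, 0.000000, 0.000000, 0.000000, 0.000000,
        0.000000, 0.000000, 0.000000, -0.000007, -0.000057, -0.000237,
        -0.001044, -0.003292, -0.007925, -0.016136, -0.029573, -0.048987,
        -0.075399, -0.109019, -0.150284, -0.198150, -0.252302, -0.313123,
        -0.380485, -0.453081, -0.530773, -0.614194, -0.700528, -0.792783,
        -0.886158, -0.984463, -1.083310, -1.187793, -1.293521, -1.401719,
        -1.513794, -1.630576, -1.747226, -1.866612, -1.990894, -2.114364,
        -2.242745, -2.370828, -2.500467, -2.635590, -2.769341, -2.905892,
        -3.045903, -3.192072, -3.344061, -3.485884, -3.634265, -3.783483,
        -3.943858, -4.102377, -4.262290, -4.430937, -4.594560, -4.758710,
        -4.930439, -5.121567, -5.299652, -5.466342, -5.656899, -5.872201,
        -6.028129, -6.209621, -6.404962, -6.595381, -6.791455, -6.991137,
        -7.169120, -7.364959, -7.563167, -7.763746, -7.966699, -8.172028,
        -8.379736, -8.589825, -8.802297, -9.017155, -9.234401, -9.454036,
        -9.676063, -9.900484, -10.127301, -10.356515, -10.588129, -10.822143,
        -11.058561, -11.297384, -11.538612, -11.782249, -12.028295, -12.276752,
        -12.527622, -12.780906, -13.036606, -13.294722, -13.555257, -13.818211,
        -14.083586, -14.351383, -14.621604, -14.894249, -15.169320, -15.446818,
        -15.726744, -16.009100, -16.293886, -16.581103, -16.870753, -17.162836,
        -17.457354, -17.754307, -18.053696, -18.355523, -18.659788, -18.966493,
        -19.275637, -19.587222, -19.901249, -20.217718, -20.536631, -20.857988,
        -21.181790, -21.508038, -21.836732, -22.167873, -22.501462, -22.837500,
        -23.175987, -23.516924, -23.860312, -24.206150, -24.554441, -24.905184,
        -25.258381, -25.614031,
    ],
    [
        0.000000, 0.000000, 0.000000, 0.000000, 0.000000, 0.000000,
        0.000000, 0.000000, 0.000000, 0.000000, -0.000033, -0.000187,
        -0.000694, -0.002530, -0.006548, -0.013916, -0.026310, -0.044478,
        -0.069082, -0.100616, -0.139645, -0.185535, -0.238113, -0.296987,
        -0.363052, -0.434338, -0.509393, -0.591102, -0.676775, -0.766155,
        -0.858832, -0.955647, -1.056569, -1.162266, -1.270160, -1.380114,
        -1.490974, -1.606525, -1.723783, -1.842232, -1.961884, -2.087823,
        -2.213384, -2.343720, -2.475273, -2.606487, -2.743988, -2.891012,
        -3.031429, -3.176375, -3.325441, -3.473446, -3.624966, -3.780702,
        -3.931716, -4.096547, -4.256628, -4.413449, -4.577879, -4.752125,
        -4.925835, -5.110456, -5.277861, -5.458486, -5.656899, -5.858100,
        -6.059030, -6.258908, -6.427389, -6.588090, -6.794427, -6.966091,
        -7.114370, -7.310208, -7.508416, -7.708995, -7.911948, -8.117277,
        -8.324985, -8.535075, -8.747547, -8.962405, -9.179650, -9.399286,
        -9.621313, -9.845734, -10.072550, -10.301764, -10.533378, -10.767393,
        -11.003811, -11.242633, -11.483862, -11.727498, -11.973545, -12.222002,
        -12.472872, -12.726156, -12.981855, -13.239971, -13.500506, -13.763460,
        -14.028835, -14.296632, -14.566853, -14.839498, -15.114570, -15.392068,
        -15.671994, -15.954349, -16.239135, -16.526353, -16.816002, -17.108086,
        -17.402603, -17.699556, -17.998946, -18.300773, -18.605038, -18.911742,
        -19.220886, -19.532471, -19.846498, -20.162968, -20.481881, -20.803238,
        -21.127040, -21.453287, -21.781981, -22.113123, -22.446712, -22.782749,
        -23.121236, -23.462173, -23.805561, -24.151400, -24.499691, -24.850434,
        -25.203630, -25.559281,
    ],
    [
        0.000000, 0.000000, 0.000000, 0.000000, 0.000000, 0.000000,
        0.000000, 0.000000, 0.000000, -0.000003, -0.000027, -0.000157,
        -0.000730, -0.002450, -0.005914, -0.012731, -0.024245, -0.041534,
        -0.065044, -0.096371, -0.134248, -0.179147, -0.231562, -0.290606,
        -0.356189, -0.426484, -0.503161, -0.584693, -0.670017, -0.758910,
        -0.852792, -0.949184, -1.049479, -1.152530, -1.258183, -1.366439,
        -1.478395, -1.592876, -1.708338, -1.828693, -1.949115, -2.072532,
        -2.199277, -2.327117, -2.461893, -2.593963, -2.729172, -2.868630,
        -3.004168, -3.145858, -3.288762, -3.437032, -3.594418, -3.745944,
        -3.904551, -4.059750, -4.220135, -4.375647, -4.535333, -4.709790,
        -4.876104, -5.037493, -5.212751, -5.387513, -5.561415, -5.744604,
        -5.916976, -6.090917, -6.265901, -6.469500, -6.655700, -6.858965,
        -7.102149, -7.245562, -7.443769, -7.644349, -7.847301, -8.052631,
        -8.260339, -8.470428, -8.682900, -8.897758, -9.115004, -9.334639,
        -9.556666, -9.781087, -10.007904, -10.237118, -10.468731, -10.702746,
        -10.939164, -11.177986, -11.419215, -11.662852, -11.908898, -12.157355,
        -12.408225, -12.661509, -12.917208, -13.175325, -13.435859, -13.698813,
        -13.964189, -14.231986, -14.502206, -14.774852, -15.049923, -15.327421,
        -15.607347, -15.889703, -16.174489, -16.461706, -16.751356, -17.043439,
        -17.337956, -17.634910, -17.934299, -18.236126, -18.540391, -18.847095,
        -19.156240, -19.467825, -19.781852, -20.098321, -20.417234, -20.738591,
        -21.062393, -21.388641, -21.717335, -22.048476, -22.382065, -22.718103,
        -23.056590, -23.397527, -23.740914, -24.086753, -24.435044, -24.785787,
        -25.138984, -25.494634,
    ],
])

LN_TAIL_ASYM = np.array([
    -0.000000, -0.000000, -0.000000, -0.000000, -0.000000, -0.000000,
    -0.000000, -0.000000, -0.000000, -0.000000, -0.000002, -0.000026,
    -0.000167, -0.000725, -0.002331, -0.005982, -0.012925, -0.024450,
    -0.041684, -0.065461, -0.096279, -0.134328, -0.179546, -0.231692,
    -0.290411, -0.355282, -0.425863, -0.501715, -0.582421, -0.667595,
    -0.756888, -0.849990, -0.946632, -1.046579, -1.149633, -1.255625,
    -1.364416, -1.475891, -1.589954, -1.706531, -1.825561, -1.946998,
    -2.070805, -2.196956, -2.325430, -2.456213, -2.589297, -2.724674,
    -2.862342, -3.002299, -3.144547, -3.289086, -3.435920, -3.585051,
    -3.736483, -3.890219, -4.046263, -4.204620, -4.365293, -4.528286,
    -4.693603, -4.861248, -5.031223, -5.203534, -5.378183, -5.555175,
    -5.734511, -5.916196, -6.100233, -6.286624, -6.475373, -6.666482,
    -6.859955, -7.055794, -7.254002, -7.454581, -7.657534, -7.862863,
    -8.070571, -8.280660, -8.493132, -8.707990, -8.925236, -9.144871,
    -9.366898, -9.591319, -9.818136, -10.047350, -10.278963, -10.512978,
    -10.749396, -10.988218, -11.229447, -11.473084, -11.719130, -11.967587,
    -12.218457, -12.471741, -12.727441, -12.985557, -13.246091, -13.509046,
    -13.774421, -14.042218, -14.312438, -14.585084, -14.860155, -15.137653,
    -15.417579, -15.699935, -15.984721, -16.271938, -16.561588, -16.853671,
    -17.148189, -17.445142, -17.744531, -18.046358, -18.350623, -18.657327,
    -18.966472, -19.278057, -19.592084, -19.908553, -20.227466, -20.548823,
    -20.872625, -21.198873, -21.527567, -21.858708, -22.192297, -22.528335,
    -22.866822, -23.207759, -23.551146, -23.896985, -24.245276, -24.596019,
    -24.949216, -25.304866,
])

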