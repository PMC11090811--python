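[
 {
  "beta": 1.343364659108,
  "se": 0.2317584615571,
  "theta": 4.2403682158,
  "sigma_station": 0.5691031007197,
  "loglik": -99.034628339719
 },
 {
  "beta": -0.0588843354848,
  "se": 0.2425269509909,
  "theta": 5.162986214959,
  "sigma_station": 0.8856073649633,
  "loglik": -97.351845370633
 },
 {
  "beta": 0.8131063057329,
  "se": 0.2565524264475,
  "theta": 2.363144468897,
  "sigma_station": 0.6405639386144,
  "loglik": -126.099906163167
 },
 {
  "beta": -0.6636956009678,
  "se": 0.1540972656245,
  "theta": 15247671.632187573,
  "sigma_station": 0.4463794866285,
  "loglik": -67.588943202025
 },
 {
  "beta": 0.2572383744501,
  "se": 0.1557292207482,
  "theta": 10.031926190056,
  "sigma_station": 0.4704323553994,
  "loglik": -115.391754909105
 },
 {
  "beta": -0.09544495577322,
  "se": 0.2105701559016,
  "theta": 3.724663371656,
  "sigma_station": 0.3430372167033,
  "loglik": -121.084806585977
 },
 {
  "beta": 0.45682113491,
  "se": 0.2082088758174,
  "theta": 3.403922345221,
  "sigma_station": 8.256756790073e-05,
  "loglik": -119.012222922224
 },
 {
  "beta": 0.3613142797603,
  "se": 0.3922219267478,
  "theta": 1.906535310595,
  "sigma_station": 0.3785618026198,
  "loglik": -66.578287723263
 },
 {
  "beta": 1.160231539564,
  "se": 0.1992593347941,
  "theta": 4.775163386694,
  "sigma_station": 0.6884844520441,
  "loglik": -122.351769485522
 },
 {
  "beta": 0.2079267399305,
  "se": 0.1791460112016,
  "theta": 4.158373714608,
  "sigma_station": 3.358268964622e-05,
  "loglik": -131.524356212468
 },
 {
  "beta": -0.2217761482266,
  "se": 0.2103953924666,
  "theta": 3.520174951872,
  "sigma_station": 0.6535004333265,
  "loglik": -132.314903513535
 },
 {
  "beta": -0.690430159717,
  "se": 0.310861723885,
  "theta": 2.579537559216,
  "sigma_station": 0.4563603991599,
  "loglik": -78.493099355362
 },
 {
  "beta": 0.8089021140728,
  "se": 0.2314439327501,
  "theta": 2.403135599541,
  "sigma_station": 0.620762310187,
  "loglik": -167.824729546833
 },
 {
  "beta": -0.1369597302246,
  "se": 0.2648983750506,
  "theta": 5.162812137698,
  "sigma_station": 0.2427309794019,
  "loglik": -57.56641143976
 },
 {
  "beta": 0.2362533280802,
  "se": 0.2231747210121,
  "theta": 2.987591860109,
  "sigma_station": 1.0035907394,
  "loglik": -154.66472651884
 },
 {
  "beta": 0.05920501588461,
  "se": 0.3893613514749,
  "theta": 0.981600202663,
  "sigma_station": 0.590050276041,
  "loglik": -138.587628668926
 },
 {
  "beta": 0.5471338219491,
  "se": 0.2198855168909,
  "theta": 2.997675367869,
  "sigma_station": 0.4254511646512,
  "loglik": -144.726499130978
 },
 {
  "beta": 0.1320179481829,
  "se": 0.2963977847736,
  "theta": 0.9956513056237,
  "sigma_station": 0.0001131749500242,
  "loglik": -198.177675495734
 },
 {
  "beta": 0.5159353835404,
  "se": 0.1962310554454,
  "theta": 2.820185332493,
  "sigma_station": 0.6680271284243,
  "loglik": -197.948762316917
 },
 {
  "beta": -0.3694523974975,
  "se": 0.3158939931496,
  "theta": 2.137758602239,
  "sigma_station": 0.5589551421125,
  "loglik": -93.979119668099
 },
 {
  "beta": -0.9505691200409,
  "se": 0.2951518738889,
  "theta": 1.497454709181,
  "sigma_station": 0.8390482009497,
  "loglik": -153.958052546257
 },
 {
  "beta": 1.253705584291,
  "se": 0.312297746445,
  "theta": 3.425413093182,
  "sigma_station": 3.08697227281e-05,
  "loglik": -58.952883836058
 },
 {
  "beta": 0.6843713117667,
  "se": 0.1886745017313,
  "theta": 3.026110708659,
  "sigma_station": 0.4763900643674,
  "loglik": -204.04401065488
 },
 {
  "beta": 0.3002388156056,
  "se": 0.2351414003476,
  "theta": 3.755130106376,
  "sigma_station": 0.641416916172,
  "loglik": -108.645073880817
 }
]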