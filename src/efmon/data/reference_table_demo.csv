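taxon,wbf_hz,mass_mg,in_europe,obs_prob
taxon_0000,190.27,3.1376,False,1.0
taxon_0001,173.42,1.382,False,1.0
taxon_0002,187.45,6.0184,True,1.0
taxon_0003,119.08,17.6529,False,1.0
taxon_0004,161.65,22.0642,True,1.0
taxon_0005,69.99,11.1486,True,1.0
taxon_0006,202.08,7.6485,True,1.0
taxon_0007,98.0,24.0402,False,1.0
taxon_0008,191.24,5.8271,True,1.0
taxon_0009,29.64,11.5988,True,1.0
taxon_0010,183.85,5.5493,True,1.0
taxon_0011,101.5,13.9269,True,1.0
taxon_0012,48.58,3.7558,True,1.0
taxon_0013,167.36,15.6172,False,1.0
taxon_0014,174.06,13.0434,False,1.0
taxon_0015,197.05,8.8858,True,1.0
taxon_0016,170.15,9.7833,True,1.0
taxon_0017,21.62,10.3776,True,1.0
taxon_0018,175.14,5.9999,True,1.0
taxon_0019,145.12,6.2452,True,1.0
taxon_0020,167.05,19.123,True,1.0
taxon_0021,188.3,9.262,True,1.0
taxon_0022,143.03,16.3374,True,1.0
taxon_0023,116.08,17.3158,True,1.0
taxon_0024,207.75,2.8849,True,1.0
taxon_0025,81.9,9.0941,True,1.0
taxon_0026,142.55,9.2269,True,1.0
taxon_0027,109.41,12.0678,True,1.0
taxon_0028,25.0,5.6739,True,1.0
taxon_0029,121.61,5.2434,True,1.0
taxon_0030,53.51,11.957,True,1.0
taxon_0031,103.82,5.4656,True,1.0
taxon_0032,99.6,2.175,True,1.0
taxon_0033,231.62,11.4643,True,1.0
taxon_0034,78.49,25.758,True,1.0
taxon_0035,177.72,3.4528,True,1.0
taxon_0036,41.21,5.8962,True,1.0
taxon_0037,64.52,11.8274,True,1.0
taxon_0038,58.89,2.1771,True,1.0
taxon_0039,178.28,9.8636,True,1.0
taxon_0040,298.41,3.2248,True,1.0
taxon_0041,281.59,4.8758,True,1.0
taxon_0042,272.99,5.515,True,1.0
taxon_0043,298.77,2.2491,False,1.0
taxon_0044,298.11,1.1587,True,1.0
taxon_0045,242.29,1.0646,True,1.0
taxon_0046,480.0,2.652,True,1.0
taxon_0047,563.87,27.5396,False,1.0
taxon_0048,603.0,0.2936,True,1.0
taxon_0049,492.53,1.3762,True,1.0
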