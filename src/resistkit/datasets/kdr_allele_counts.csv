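site,period,status,locus,count_wildtype,count_mutant,printed_f,printed_ci_low,printed_ci_high
VK7,Jul-11,control,L1014F,22,102,0.823,0.744,0.886
VK7,Jul-11,control,N1575Y,80,44,0.355,0.276,0.442
VK7,Jul-11,dead,L1014F,23,97,0.808,0.728,0.870
VK7,Jul-11,dead,N1575Y,92,34,0.270,0.200,0.354
VK7,Jul-11,survivor,L1014F,19,95,0.833,0.754,0.892
VK7,Jul-11,survivor,N1575Y,80,30,0.273,0.198,0.363
VK7,Oct-11,control,L1014F,27,163,0.858,0.801,0.901
VK7,Oct-11,control,N1575Y,134,56,0.295,0.234,0.363
VK7,Oct-11,dead,L1014F,42,194,0.822,0.768,0.866
VK7,Oct-11,dead,N1575Y,174,60,0.256,0.205,0.316
VK7,Oct-11,survivor,L1014F,15,133,0.899,0.839,0.939
VK7,Oct-11,survivor,N1575Y,91,55,0.377,0.302,0.458
VK7,Jun-12,control,L1014F,25,183,0.880,0.828,0.918
VK7,Jun-12,control,N1575Y,151,55,0.267,0.211,0.331
VK7,Jun-12,dead,L1014F,9,45,0.833,0.710,0.912
VK7,Jun-12,dead,N1575Y,42,12,0.222,0.131,0.351
VK7,Jun-12,survivor,L1014F,14,132,0.904,0.844,0.943
VK7,Jun-12,survivor,N1575Y,90,56,0.384,0.309,0.465
VK7,Jul-13,control,L1014F,16,126,0.887,0.823,0.934
VK7,Jul-13,control,N1575Y,109,33,0.232,0.166,0.311
Tengrela,Jul-12,control,L1014F,14,100,0.877,0.803,0.931
Tengrela,Jul-12,control,N1575Y,87,27,0.237,0.162,0.326
Tengrela,Jul-12,dead,L1014F,18,80,0.816,0.725,0.887
Tengrela,Jul-12,dead,N1575Y,66,32,0.327,0.235,0.429
Tengrela,Jul-12,survivor,L1014F,11,81,0.880,0.796,0.939
Tengrela,Jul-12,survivor,N1575Y,66,26,0.283,0.194,0.386
Tengrela,Jul-13,control,L1014F,24,124,0.838,0.768,0.893
Tengrela,Jul-13,control,N1575Y,109,39,0.264,0.194,0.342
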