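subject_id	s001	s002	s003	s004	s005	s006	s007	s008	s009	s010	s011	s012
s001	1	0.184025143088	0.100586459422	0.158288910879	0.145683377324	0.104516819714	0	0	0	0.0411665576103	0.104516819714	0
s002	0.184025143088	1	0.14923590504	0.0898160032277	0.176542255081	0.14923590504	0	0	0	0	0	0
s003	0.100586459422	0.14923590504	1	0.235499380552	0.194332822942	0.0972988912348	0	0	0	0.0759557956585	0	0
s004	0.158288910879	0.0898160032277	0.235499380552	1	0.14923590504	0.124605241276	0	0	0	0	0	0.0486494456174
s005	0.145683377324	0.176542255081	0.194332822942	0.14923590504	1	0.252624594809	0	0	0	0	0	0
s006	0.104516819714	0.14923590504	0.0972988912348	0.124605241276	0.252624594809	1	0.104516819714	0.0759557956585	0	0	0.0759557956585	0
s007	0	0	0	0	0	0.104516819714	1	0.172149118448	0.179632006455	0.108069347429	0.225191700698	0.100586459422
s008	0	0	0	0	0	0.0759557956585	0.172149118448	1	0.167489249241	0.225191700698	0.199455468489	0.130982560838
s009	0	0	0	0	0	0	0.179632006455	0.167489249241	1	0.0411665576103	0.266358258309	0.19040246265
s010	0.0411665576103	0	0.0759557956585	0	0	0	0.108069347429	0.225191700698	0.0411665576103	1	0.100586459422	0.153166265331
s011	0.104516819714	0	0	0	0	0.0759557956585	0.225191700698	0.199455468489	0.266358258309	0.100586459422	1	0.0411665576103
s012	0	0	0	0.0486494456174	0	0	0.100586459422	0.130982560838	0.19040246265	0.153166265331	0.0411665576103	1
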