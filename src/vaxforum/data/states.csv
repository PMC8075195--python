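state,abbrev,population_2010
Alabama,AL,4779736
Alaska,AK,710231
Arizona,AZ,6392017
Arkansas,AR,2915918
California,CA,37253956
Colorado,CO,5029196
Connecticut,CT,3574097
Delaware,DE,897934
District of Columbia,DC,601723
Florida,FL,18801310
Georgia,GA,9687653
Hawaii,HI,1360301
Idaho,ID,1567582
Illinois,IL,12830632
Indiana,IN,6483802
Iowa,IA,3046355
Kansas,KS,2853118
Kentucky,KY,4339367
Louisiana,LA,4533372
Maine,ME,1328361
Maryland,MD,5773552
Massachusetts,MA,6547629
Michigan,MI,9883640
Minnesota,MN,5303925
Mississippi,MS,2967297
Missouri,MO,5988927
Montana,MT,989415
Nebraska,NE,1826341
Nevada,NV,2700551
New Hampshire,NH,1316470
New Jersey,NJ,8791894
New Mexico,NM,2059179
New York,NY,19378102
North Carolina,NC,9535483
North Dakota,ND,672591
Ohio,OH,11536504
Oklahoma,OK,3751351
Oregon,OR,3831074
Pennsylvania,PA,12702379
Rhode Island,RI,1052567
South Carolina,SC,4625364
South Dakota,SD,814180
Tennessee,TN,6346105
Texas,TX,25145561
Utah,UT,2763885
Vermont,VT,625741
Virginia,VA,8001024
Washington,WA,6724540
West Virginia,WV,1852994
Wisconsin,WI,5686986
Wyoming,WY,563626
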